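"""Degraded-retinotopy model: RF-position jitter and Kendall's tau.

The baseline Monte Carlo model assumes perfect retinotopy.  Here the map
is degraded by adding independent per-axis Gaussian noise to each RF
position, with standard deviation sigma x 135 deg — sigma = 1 thus
corresponds to the full represented visual field (equivalently the full
300 um width of the optic tract).  For each sigma on a grid (default 0
to 0.5 in steps of 0.05) nearby pairs are simulated: a probe position is
drawn in the visual-stimulation area (73 x 44 deg), two ideal RF
positions are drawn within the recording range around it, jitter is
added, and the trial is eliminated if either jittered RF falls outside
the stimulation area.  The degree of retinotopy at each sigma is
summarised by Kendall's tau between ideal and jittered positions
(axis-averaged), and the jitter level of a measured preparation is
estimated by intersecting its measured nearby-pair median RF distance
with the simulated median-vs-sigma curve.

Conversions are exact identities:
``deviation_deg = sigma* x 135`` and ``displacement_um = sigma* x 300``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .population import FIELD_SPAN_DEG, GRADIENT_OT, TRACT_DIAMETER_UM
from .stimulus import STIM_EXTENT_DEG


@dataclass
class JitterConfig:
    sigma_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 0.501, 0.05), 10)
    )
    field_span_deg: float = FIELD_SPAN_DEG
    tract_width_um: float = TRACT_DIAMETER_UM
    stim_area_deg: tuple[float, float] = STIM_EXTENT_DEG
    recording_range_um: float = 20.0
    exclusion_um: float = 2.0
    g_deg_per_um: float = GRADIENT_OT
    trials_per_sigma: int = 39_000
    tau_axons: int = 2_000
    tau_repeats: int = 20
    geometry: str = "disk2d"  # or "ball3d"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=float)
        if (self.sigma_grid < 0).any():
            raise ValueError("sigma values must be >= 0")
        if self.geometry not in ("disk2d", "ball3d"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def range_deg(self) -> float:
        """Recording range mapped to visual degrees (disk radius)."""
        return self.recording_range_um * self.g_deg_per_um


def _ideal_pair_offsets(
    m: int, cfg: JitterConfig, rng: np.random.Generator
) -> np.ndarray:
    """(m, 2, 2) ideal RF offsets of pair members around their probe.

    ``disk2d`` draws each member uniformly in the disk of radius
    r x g in the visual plane; ``ball3d`` draws the pair in the physical
    3D ball of radius r and projects the cross-sectional components.
    Pairs separated by less than the exclusion threshold (x g) are
    redrawn.
    """
    d_min = cfg.exclusion_um * cfg.g_deg_per_um
    out = np.empty((m, 2, 2))
    filled = 0
    while filled < m:
        k = max(int(1.2 * (m - filled)) + 16, 16)
        if cfg.geometry == "disk2d":
            rad = cfg.range_deg * np.sqrt(rng.uniform(size=(k, 2)))
            th = rng.uniform(0, 2 * np.pi, size=(k, 2))
            pts = np.stack(
                [rad * np.cos(th), rad * np.sin(th)], axis=-1
            )  # (k, 2, 2)
        else:
            v = rng.standard_normal((k, 2, 3))
            v /= np.linalg.norm(v, axis=2, keepdims=True)
            v *= cfg.recording_range_um * rng.uniform(size=(k, 2, 1)) ** (1 / 3)
            pts = v[:, :, :2] * cfg.g_deg_per_um
        sep = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
        pts = pts[sep > d_min][: m - filled]
        out[filled : filled + len(pts)] = pts
        filled += len(pts)
    return out


def simulate_jittered_pairs(
    sigma: float,
    cfg: JitterConfig,
    rng: np.random.Generator,
    n_accepted: int,
) -> tuple[np.ndarray, float]:
    """Accepted nearby-pair RF distances at one jitter level.

    Probe positions are drawn uniformly from the stimulation area eroded
    by the recording range (in degrees) so that ideal RFs always lie
    inside the area and trials are eliminated only because of the added
    jitter.  Returns (distances, rejection_fraction).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    w, h = cfg.stim_area_deg
    R = cfg.range_deg
    if w <= 2 * R or h <= 2 * R:
        raise ValueError("stimulation area too small for the recording range")
    half = np.array([w / 2 - R, h / 2 - R])
    lim = np.array([w / 2, h / 2])
    noise_sd = sigma * cfg.field_span_deg

    dists = np.empty(n_accepted)
    filled = 0
    n_total = 0
    n_acc_total = 0
    est_acc = 1.0  # running acceptance estimate drives the batch size
    while filled < n_accepted:
        k = min(int((n_accepted - filled) / est_acc * 1.2) + 64, 4_000_000)
        probe = rng.uniform(-half, half, size=(k, 1, 2))
        pts = probe + _ideal_pair_offsets(k, cfg, rng)
        if noise_sd > 0:
            pts = pts + noise_sd * rng.standard_normal(pts.shape)
        inside = (np.abs(pts) <= lim).all(axis=(1, 2))
        n_total += k
        acc = pts[inside]
        n_acc_total += len(acc)
        est_acc = max(n_acc_total / n_total, 1e-4)
        if n_total > 10_000 * max(n_acc_total, 1):
            raise RuntimeError(
                f"acceptance rate below 0.01% at sigma={sigma}; stimulation "
                "area too small relative to the jitter"
            )
        acc = acc[: n_accepted - filled]
        dists[filled : filled + len(acc)] = np.linalg.norm(
            acc[:, 0] - acc[:, 1], axis=1
        )
        filled += len(acc)
    return dists, 1.0 - n_acc_total / n_total


def simulate_jittered_pair(
    sigma: float, cfg: JitterConfig, rng: np.random.Generator
) -> float | None:
    """Single trial; returns the RF distance in degrees or None if rejected."""
    w, h = cfg.stim_area_deg
    R = cfg.range_deg
    half = np.array([w / 2 - R, h / 2 - R])
    lim = np.array([w / 2, h / 2])
    probe = rng.uniform(-half, half)
    pts = probe + _ideal_pair_offsets(1, cfg, rng)[0]
    pts = pts + sigma * cfg.field_span_deg * rng.standard_normal((2, 2))
    if not (np.abs(pts) <= lim).all():
        return None
    return float(np.linalg.norm(pts[0] - pts[1]))


def compute_tau(
    sigma: float, cfg: JitterConfig, rng: np.random.Generator
) -> float:
    """Kendall's tau spatial-monotonicity index at one jitter level.

    ``tau_axons`` ideal RF positions are drawn uniformly over the
    stimulation area, jittered, and Kendall's tau between ideal and
    jittered coordinates is computed per axis; the two axis values are
    averaged, and the whole procedure repeated ``tau_repeats`` times.
    tau = 1 at sigma = 0 (monotone identity), ~0 for noise-dominated maps.
    """
    if sigma == 0:
        return 1.0
    w, h = cfg.stim_area_deg
    noise_sd = sigma * cfg.field_span_deg
    taus = []
    for _ in range(cfg.tau_repeats):
        ideal = rng.uniform([-w / 2, -h / 2], [w / 2, h / 2], size=(cfg.tau_axons, 2))
        jittered = ideal + noise_sd * rng.standard_normal(ideal.shape)
        for ax in range(2):
            taus.append(stats.kendalltau(ideal[:, ax], jittered[:, ax]).statistic)
    return float(np.mean(taus))


def tau_normal_approx(sigma: float, cfg: JitterConfig | None = None) -> float:
    """Greiner-relation approximation tau = (2/pi) asin(rho), axis-averaged.

    rho per axis follows from the variance of a uniform position on the
    stimulation area vs the jitter variance; exact for bivariate normal
    inputs, a close approximation for the uniform positions used here.
    """
    if cfg is None:
        cfg = JitterConfig()
    if sigma == 0:
        return 1.0
    noise_var = (sigma * cfg.field_span_deg) ** 2
    taus = []
    for span in cfg.stim_area_deg:
        pos_var = span**2 / 12.0
        rho = np.sqrt(pos_var / (pos_var + noise_var))
        taus.append(2.0 / np.pi * np.arcsin(rho))
    return float(np.mean(taus))


def sweep_sigma(cfg: JitterConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-sigma curve: median/quartiles of RF distance, rejection rate, tau."""
    if len(cfg.sigma_grid) == 0:
        raise ValueError("sigma grid must be nonempty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows = []
    for sigma in cfg.sigma_grid:
        d, rej = simulate_jittered_pairs(sigma, cfg, rng, cfg.trials_per_sigma)
        q25, med, q75 = np.percentile(d, [25, 50, 75])
        rows.append(
            dict(
                sigma=float(sigma),
                median_deg=float(med),
                q25_deg=float(q25),
                q75_deg=float(q75),
                rejection_rate=float(rej),
                tau=compute_tau(float(sigma), cfg, rng),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class RetinotopyEstimate:
    sigma_star: float
    tau_star: float
    deviation_deg: float
    displacement_um: float
    measured_median_deg: float
    curve: pd.DataFrame

    def to_dict(self) -> dict:
        return dict(
            sigma_star=self.sigma_star,
            tau_star=self.tau_star,
            deviation_deg=self.deviation_deg,
            displacement_um=self.displacement_um,
            measured_median_deg=self.measured_median_deg,
        )


def estimate_retinotopy(
    measured_median_deg: float,
    curve: pd.DataFrame,
    cfg: JitterConfig | None = None,
) -> RetinotopyEstimate:
    """Intersect a measured nearby-pair median with the simulated curve.

    sigma* is found by linear interpolation of the median-vs-sigma curve
    at the measured value, tau* by interpolating the tau-vs-sigma curve
    at sigma*.  A measured median outside the curve's range raises, with
    the bracketing values reported.
    """
    if cfg is None:
        cfg = JitterConfig()
    c = curve.sort_values("sigma").reset_index(drop=True)
    med = c["median_deg"].to_numpy()
    sig = c["sigma"].to_numpy()
    m = float(measured_median_deg)
    if m < med[0] or m > med[-1]:
        raise ValueError(
            f"measured median {m:.2f} deg is outside the simulated range "
            f"[{med[0]:.2f}, {med[-1]:.2f}] deg; extend the sigma grid"
        )
    # first bracketing interval on the (noisily monotone) median curve
    i = int(np.searchsorted(med, m, side="left"))
    if i == 0:
        sigma_star = float(sig[0])
    else:
        lo, hi = med[i - 1], med[i]
        frac = 0.0 if hi == lo else (m - lo) / (hi - lo)
        sigma_star = float(sig[i - 1] + frac * (sig[i] - sig[i - 1]))
    tau_star = float(np.interp(sigma_star, sig, c["tau"].to_numpy()))
    return RetinotopyEstimate(
        sigma_star=sigma_star,
        tau_star=tau_star,
        deviation_deg=sigma_star * cfg.field_span_deg,
        displacement_um=sigma_star * cfg.tract_width_um,
        measured_median_deg=m,
        curve=c,
    )
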