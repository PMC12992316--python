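"""Ground-truth model units with a retinotopic position -> RF mapping.

Units are linear-nonlinear Poisson (LN) neurons.  Each unit has a physical
position in the recorded volume, a separable spatiotemporal receptive
field (elliptical 2D-Gaussian spatial profile, biphasic temporal kernel)
and an ON or OFF polarity.  The ideal RF centre is an affine image of the
cross-sectional (x, y) position under the retinotopy gradient g; optional
Gaussian jitter with per-axis s.d. ``jitter_sigma`` x 135 deg degrades the
map, emulating axonal displacement in the fibre bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .probe import ProbeGeometry, default_probe
from .stimulus import STIM_EXTENT_DEG

#: full span of the represented visual field, degrees (jitter sigma = 1)
FIELD_SPAN_DEG = 135.0
#: optic-tract diameter, micrometres (jitter sigma = 1 equivalently)
TRACT_DIAMETER_UM = 300.0
#: retinotopy gradients, degrees of visual field per micrometre of tissue
GRADIENT_OT = FIELD_SPAN_DEG / TRACT_DIAMETER_UM  # 0.45
GRADIENT_LGN = 0.11

#: single-unit recording range (max cell-to-electrode distance), micrometres
RECORDING_RANGE_UM = {"OT": 20.0, "LGN": 40.0}

N_LAGS = 30  # temporal kernel length at dt = 1/60 s

# Median RF size (1-sigma diameter mean, deg) and peak latency (ms) with
# their median absolute deviations, by (mode, polarity) — the measured
# summary statistics the generator reproduces.
RF_SIZE_STATS = {
    ("OT", "ON"): (3.6, 0.9),
    ("OT", "OFF"): (3.5, 0.9),
    ("LGN", "ON"): (4.7, 1.2),
    ("LGN", "OFF"): (4.3, 1.0),
}
LATENCY_STATS = {
    ("OT", "ON"): (46.0, 5.0),
    ("OT", "OFF"): (51.0, 8.0),
    ("LGN", "ON"): (46.0, 4.0),
    ("LGN", "OFF"): (46.0, 5.0),
}


@dataclass
class GroundTruthPopulation:
    """Arrays describing ``n_units`` simulated neurons (row per unit)."""

    position_um: np.ndarray        # (n, 3)
    rf_center_deg: np.ndarray      # (n, 2) jittered (azimuth, elevation)
    rf_center_ideal_deg: np.ndarray  # (n, 2) pre-jitter affine image
    rf_sigma_deg: np.ndarray       # (n, 2) (sigma_major, sigma_minor)
    rf_orientation: np.ndarray     # (n,) radians, major-axis angle
    polarity: np.ndarray           # (n,) +1 = ON, -1 = OFF
    temporal_kernel: np.ndarray    # (n, N_LAGS), unit L2 norm, lag 0 = spike time
    baseline_rate: np.ndarray      # (n,) Hz
    gain: np.ndarray               # (n,) Hz per s.d. of filter drive
    mode: str = "OT"
    jitter_sigma: float = 0.0

    @property
    def n_units(self) -> int:
        return self.position_um.shape[0]

    @property
    def rf_size_deg(self) -> np.ndarray:
        """Mean of long/short axis diameters at 1 sigma."""
        return self.rf_sigma_deg.sum(axis=1)

    def kernel_peak_latency_s(self) -> np.ndarray:
        """Ground-truth peak latency: lag of the kernel extremum x dt."""
        lag = np.abs(self.temporal_kernel).argmax(axis=1)
        return lag / 60.0


def _lognormal_around(median: float, mad: float, size, rng) -> np.ndarray:
    # Log-normal with the requested median; sigma chosen so the MAD of the
    # small-spread approximation matches (|e^{sZ}-1| ~ 0.6745 s near s=0).
    s = mad / (0.6745 * median)
    return median * np.exp(s * rng.standard_normal(size))


def _biphasic_kernel(peak_s: np.ndarray, dt_s: float = 1 / 60) -> np.ndarray:
    """Biphasic temporal kernels, one row per unit, unit L2 norm.

    Positive lobe at ``peak_s`` before the spike, weaker opposite lobe
    ~55 ms later; single dominant extremum by construction.
    """
    t = (np.arange(N_LAGS) * dt_s)[None, :]
    tp = np.asarray(peak_s)[:, None]
    k = np.exp(-0.5 * ((t - tp) / 0.015) ** 2)
    k -= 0.45 * np.exp(-0.5 * ((t - tp - 0.055) / 0.030) ** 2)
    k /= np.linalg.norm(k, axis=1, keepdims=True)
    return k


def build_population(
    n_units: int,
    mode: str = "OT",
    jitter_sigma: float = 0.0,
    geometry: ProbeGeometry | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    max_site_distance_um: float | None = None,
    require_rf_in_stim: bool = True,
    map_center_deg: tuple[float, float] = (0.0, 0.0),
    baseline_rate_hz: float = 0.5,
    gain_hz: float = 20.0,
) -> GroundTruthPopulation:
    """Draw a ground-truth population for one simulated session.

    OT units are placed uniformly in a cylinder of diameter 300 um whose
    axis runs along the tract (z); LGN units in a box spanning the probe.
    The ideal RF centre is ``map_center_deg + g x (x, y)`` — an affine
    image of the cross-sectional position; Gaussian jitter with per-axis
    s.d. ``jitter_sigma`` x 135 deg is then added.  ``map_center_deg``
    is the visual-field location the probe insertion point represents;
    drawing it at random across sessions emulates independent probe
    placements in different animals.

    By default unit positions are additionally constrained to lie within
    the single-unit recording range of at least one site
    (``max_site_distance_um``, 20 um OT / 40 um LGN) and to have their
    ideal RF centre inside the stimulation area — only such units are
    isolatable and mappable in a real session.  Pass
    ``max_site_distance_um=np.inf`` / ``require_rf_in_stim=False`` to lift
    the constraints.
    """
    mode = mode.upper()
    if mode not in ("OT", "LGN"):
        raise ValueError(f"mode must be 'OT' or 'LGN', got {mode!r}")
    if n_units < 0:
        raise ValueError("n_units must be >= 0")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if geometry is None:
        geometry = default_probe()
    if max_site_distance_um is None:
        max_site_distance_um = RECORDING_RANGE_UM[mode]

    # OT: fibres run along z, so the map depends on the cross-section (x, y).
    # LGN: a nucleus has no invariant axis; the gradient is aligned with the
    # plane the probe samples (shank spread z, site spread y).
    if mode == "OT":
        g, map_axes = GRADIENT_OT, (0, 1)
    else:
        g, map_axes = GRADIENT_LGN, (2, 1)
    sites = geometry.site_positions
    half_az, half_el = STIM_EXTENT_DEG[0] / 2, STIM_EXTENT_DEG[1] / 2
    margin = max(max_site_distance_um, 40.0) if np.isfinite(max_site_distance_um) else 40.0
    z_lo, z_hi = sites[:, 2].min() - margin, sites[:, 2].max() + margin

    def propose(m: int) -> np.ndarray:
        if mode == "OT":
            r = (TRACT_DIAMETER_UM / 2) * np.sqrt(rng.uniform(size=m))
            th = rng.uniform(0, 2 * np.pi, size=m)
            xy = np.c_[r * np.cos(th), r * np.sin(th)]
        else:
            xy = np.c_[
                rng.uniform(sites[:, 0].min() - margin, sites[:, 0].max() + margin, size=m),
                rng.uniform(sites[:, 1].min() - margin, sites[:, 1].max() + margin, size=m),
            ]
        z = rng.uniform(z_lo, z_hi, size=m)
        return np.c_[xy, z]

    accepted: list[np.ndarray] = []
    n_have = 0
    for _ in range(1000):
        if n_have >= n_units:
            break
        cand = propose(max(4 * (n_units - n_have), 64))
        keep = np.ones(len(cand), dtype=bool)
        if np.isfinite(max_site_distance_um):
            d = np.linalg.norm(cand[:, None, :] - sites[None, :, :], axis=2)
            keep &= d.min(axis=1) <= max_site_distance_um
        if require_rf_in_stim:
            rf = np.asarray(map_center_deg) + g * cand[:, map_axes]
            keep &= (np.abs(rf[:, 0]) <= half_az) & (np.abs(rf[:, 1]) <= half_el)
        cand = cand[keep]
        accepted.append(cand)
        n_have += len(cand)
    pos = (
        np.concatenate(accepted)[:n_units]
        if accepted
        else np.empty((0, 3))
    )
    if pos.shape[0] < n_units:
        raise RuntimeError(
            "could not place units under the site-distance / stimulus-area "
            "constraints; relax them or enlarge the geometry"
        )

    ideal = np.asarray(map_center_deg) + g * pos[:, map_axes]
    jitter = jitter_sigma * FIELD_SPAN_DEG * rng.standard_normal((n_units, 2))
    center = ideal + jitter

    polarity = rng.choice([1, -1], size=n_units)
    size = np.empty(n_units)
    latency_ms = np.empty(n_units)
    for pol_val, pol_name in ((1, "ON"), (-1, "OFF")):
        m = polarity == pol_val
        if m.any():
            med, mad = RF_SIZE_STATS[(mode, pol_name)]
            size[m] = _lognormal_around(med, mad, int(m.sum()), rng)
            med, mad = LATENCY_STATS[(mode, pol_name)]
            latency_ms[m] = _lognormal_around(med, mad, int(m.sum()), rng)
    # split size = sigma_major + sigma_minor with a mild random aspect ratio
    aspect = rng.uniform(1.0, 1.6, size=n_units)
    sig_minor = size / (1 + aspect)
    sig_major = size - sig_minor
    orientation = rng.uniform(0, np.pi, size=n_units)

    kernels = _biphasic_kernel(latency_ms / 1000.0) if n_units else np.empty((0, N_LAGS))

    return GroundTruthPopulation(
        position_um=pos,
        rf_center_deg=center,
        rf_center_ideal_deg=ideal,
        rf_sigma_deg=np.c_[sig_major, sig_minor] if n_units else np.empty((0, 2)),
        rf_orientation=orientation,
        polarity=polarity,
        temporal_kernel=kernels,
        baseline_rate=np.full(n_units, float(baseline_rate_hz)),
        gain=np.full(n_units, float(gain_hz)),
        mode=mode,
        jitter_sigma=float(jitter_sigma),
    )
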