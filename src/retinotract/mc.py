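"""Baseline Monte Carlo model of nearby-pair RF distance under retinotopy.

Two cells recorded on the same electrode both lie within the single-unit
recording range r of it; under perfect retinotopy with gradient g their
RF distance is D x g, where D is the physical separation of two points
drawn uniformly in a ball of radius r, subject to D exceeding an
exclusion threshold d (the physical size of the neurons/axons).  The
procedure is repeated 1,000 x n times, where n is the size of the
empirical sample whose median the prediction is compared with, and the
95% confidence interval of the median of a sample of size n is taken as
the 2.5/97.5 percentiles of the 1,000 per-replicate medians.

Presets::

    OT  : r = 20 um, d =  2 um (RGC axon diameter), g = 0.45 deg/um, n = 39
    LGN : r = 40 um, d = 10 um (cell body size),    g = 0.11 deg/um, n = 150
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: paper-scale parameter presets: r_um, d_um, g_deg_per_um, n
PRESETS = {
    "ot": dict(r_um=20.0, d_um=2.0, g_deg_per_um=0.45, n=39),
    "lgn": dict(r_um=40.0, d_um=10.0, g_deg_per_um=0.11, n=150),
}


@dataclass
class MCConfig:
    r_um: float
    d_um: float
    g_deg_per_um: float
    n: int
    reps: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.d_um < 2 * self.r_um):
            raise ValueError(
                f"exclusion threshold d={self.d_um} must satisfy "
                f"0 <= d < 2r = {2 * self.r_um}"
            )
        if self.g_deg_per_um < 0:
            raise ValueError("gradient g must be >= 0")
        if self.n < 1:
            raise ValueError("sample size n must be >= 1")

    @classmethod
    def preset(cls, name: str, reps: int = 1000, seed: int | None = None) -> "MCConfig":
        return cls(**PRESETS[name.lower()], reps=reps, seed=seed)


@dataclass
class MCPrediction:
    samples_deg: np.ndarray      # (reps, n)
    median_deg: float            # pooled over reps x n
    median_of_medians_deg: float
    ci95_deg: tuple[float, float]
    config: MCConfig

    def to_dict(self) -> dict:
        return dict(
            median_deg=self.median_deg,
            median_of_medians_deg=self.median_of_medians_deg,
            ci95_low_deg=self.ci95_deg[0],
            ci95_high_deg=self.ci95_deg[1],
            r_um=self.config.r_um,
            d_um=self.config.d_um,
            g_deg_per_um=self.config.g_deg_per_um,
            n=self.config.n,
            reps=self.config.reps,
        )


def _uniform_ball(n: int, r: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * (r * rng.uniform(size=(n, 1)) ** (1 / 3))


def sample_pair_distances(
    n: int, r_um: float, d_um: float, rng: np.random.Generator
) -> np.ndarray:
    """``n`` separations of point pairs uniform in the ball of radius r.

    Pairs closer than the exclusion threshold d are redrawn, so every
    returned value lies in (d, 2r].
    """
    if not (0 <= d_um < 2 * r_um):
        raise ValueError("need 0 <= d < 2r")
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(n - filled, 1)
        # oversample to cover the rejection rate of small separations
        m_draw = int(1.2 * m) + 16
        d = np.linalg.norm(
            _uniform_ball(m_draw, r_um, rng) - _uniform_ball(m_draw, r_um, rng),
            axis=1,
        )
        d = d[d > d_um][: n - filled]
        out[filled : filled + len(d)] = d
        filled += len(d)
    return out


def sample_pair_distance(r_um: float, d_um: float, rng: np.random.Generator) -> float:
    """Single draw of the pair separation (see :func:`sample_pair_distances`)."""
    return float(sample_pair_distances(1, r_um, d_um, rng)[0])


def predict_rf_distance(
    config: MCConfig, rng: np.random.Generator | None = None
) -> MCPrediction:
    """Monte Carlo prediction of the nearby-pair RF-distance distribution."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = sample_pair_distances(config.reps * config.n, config.r_um, config.d_um, rng)
    samples = (d * config.g_deg_per_um).reshape(config.reps, config.n)
    rep_medians = np.median(samples, axis=1)
    lo, hi = np.percentile(rep_medians, [2.5, 97.5])
    return MCPrediction(
        samples_deg=samples,
        median_deg=float(np.median(samples)),
        median_of_medians_deg=float(np.median(rep_medians)),
        ci95_deg=(float(lo), float(hi)),
        config=config,
    )


# -- closed-form oracle helpers (pair distance in a ball, d = 0) -----------

def ball_pair_distance_mean(r: float) -> float:
    """Exact mean separation of two uniform points in a ball: 36r/35."""
    return 36.0 * r / 35.0


def ball_pair_distance_cdf(s, r: float):
    """Exact CDF of the separation: F(s) = s^3/r^3 - 9s^4/(16r^4) + s^6/(32r^6)."""
    s = np.asarray(s, dtype=float)
    x = np.clip(s / r, 0.0, 2.0)
    return x**3 - 9 * x**4 / 16 + x**6 / 32
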