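"""LN-Poisson spike generation and extracellular amplitude model.

Each unit's drive is its separable spatiotemporal filter applied to the
stimulus history, normalised to unit variance; the instantaneous rate is
``baseline + gain * max(drive, 0)`` and spike counts per frame are
Poisson.  Extracellular spike amplitude on a recording site falls off as
the inverse of the unit-site distance, and the dominant site is the
nearest one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .population import GroundTruthPopulation, N_LAGS
from .probe import ProbeGeometry
from .stimulus import StimulusMovie

logger = logging.getLogger(__name__)

#: amplitude scale: k / distance_um, so ~100 (a.u.) at 20 um
AMPLITUDE_K = 2000.0
MIN_DISTANCE_UM = 1.0


@dataclass
class SpikeData:
    """Spike trains and per-site amplitudes for one simulated session."""

    spike_times_s: list[np.ndarray]   # per unit, sorted
    site_amplitudes: np.ndarray       # (n_units, n_sites)
    dominant_site: np.ndarray         # (n_units,) int
    rf_outside_stim: np.ndarray       # (n_units,) bool flag
    duration_s: float

    @property
    def n_units(self) -> int:
        return len(self.spike_times_s)

    def spike_counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.spike_times_s])


def spatial_profile(
    unit: int, pop: GroundTruthPopulation, stim: StimulusMovie
) -> np.ndarray:
    """Signed spatial RF of ``unit`` sampled on the pixel grid.

    Normalised by the L2 norm of the *full* (untruncated) Gaussian, so a
    fully covered RF gives ~unit-variance drive while an RF falling
    outside the stimulated area contributes only its (vanishing) tail —
    truncation reduces the drive instead of being renormalised away.
    """
    az, el = stim.pixel_centers_deg()
    AZ, EL = np.meshgrid(az, el)
    cx, cy = pop.rf_center_deg[unit]
    sa, sb = pop.rf_sigma_deg[unit]
    th = pop.rf_orientation[unit]
    u = (AZ - cx) * np.cos(th) + (EL - cy) * np.sin(th)
    v = -(AZ - cx) * np.sin(th) + (EL - cy) * np.cos(th)
    prof = np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))
    # ||G||_2^2 of the continuous Gaussian per unit pixel area
    pix_area = stim.pixel_size_deg[0] * stim.pixel_size_deg[1]
    full_norm = np.sqrt(np.pi * sa * sb / pix_area)
    prof = prof / full_norm
    return pop.polarity[unit] * prof


def assign_site_amplitudes(
    pop: GroundTruthPopulation, geometry: ProbeGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-distance amplitudes and the dominant (nearest) site.

    Distances are clamped at 1 um so that a unit sitting on a site does
    not produce an infinite amplitude; clamping is logged.
    """
    d = np.linalg.norm(
        pop.position_um[:, None, :] - geometry.site_positions[None, :, :], axis=2
    )
    n_clamped = int((d < MIN_DISTANCE_UM).sum())
    if n_clamped:
        logger.info("clamped %d unit-site distances to %g um", n_clamped, MIN_DISTANCE_UM)
    d = np.maximum(d, MIN_DISTANCE_UM)
    amps = AMPLITUDE_K / d
    return amps, amps.argmax(axis=1)


def simulate_spikes(
    pop: GroundTruthPopulation,
    stim: StimulusMovie,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    geometry: ProbeGeometry | None = None,
) -> SpikeData:
    """Simulate Poisson spike trains for every unit under ``stim``.

    Units whose RF centre lies outside the stimulated area are flagged
    (``rf_outside_stim``) and a warning is emitted; they are still
    simulated (their drive is essentially zero, so they fire near
    baseline), matching what a recording of such a unit would look like.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_frames = stim.n_frames
    dt = stim.dt_s
    frames_flat = stim.frames.reshape(n_frames, -1).astype(np.float32)

    outside = np.array(
        [not stim.covers(*pop.rf_center_deg[i]) for i in range(pop.n_units)]
    )
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} unit(s) have RF centres outside the "
            "stimulated area; they are flagged, not dropped",
            stacklevel=2,
        )

    spike_times: list[np.ndarray] = []
    for i in range(pop.n_units):
        prof = spatial_profile(i, pop, stim).astype(np.float32)
        s = frames_flat @ prof.ravel()  # (n_frames,) unit-variance-ish drive
        k = pop.temporal_kernel[i]
        # drive[t] = sum_l k[l] * s[t - l]; valid from frame N_LAGS-1 on
        u = np.convolve(s, k, mode="full")[: n_frames]
        u[: N_LAGS - 1] = 0.0  # incomplete history: baseline only
        rate = pop.baseline_rate[i] + pop.gain[i] * np.maximum(u, 0.0)
        counts = rng.poisson(rate * dt)
        idx = np.nonzero(counts)[0]
        t = np.repeat(idx, counts[idx]) * dt + rng.uniform(
            0, dt, size=int(counts.sum())
        )
        spike_times.append(np.sort(t))

    if geometry is not None:
        amps, dom = assign_site_amplitudes(pop, geometry)
    else:
        amps = np.zeros((pop.n_units, 0))
        dom = np.full(pop.n_units, -1)
    return SpikeData(
        spike_times_s=spike_times,
        site_amplitudes=amps,
        dominant_site=dom,
        rf_outside_stim=outside,
        duration_s=stim.duration_s,
    )
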