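"""Multi-session synthetic studies.

The measured pair statistics pool recordings from many animals, each
with an independent probe insertion that lands at a different point of
the retinotopic map.  :func:`run_synthetic_study` emulates this: each
session draws a random map centre (the visual-field location represented
at the insertion point), simulates a recording, maps the RFs and
enumerates the unit pairs; pairs are pooled across sessions but never
formed between them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import pairs as pairs_mod
from . import population, probe, rfmap, simulate, stimulus
from .stimulus import STIM_EXTENT_DEG


def run_synthetic_study(
    jitter_sigma: float,
    n_sessions: int = 6,
    units_per_session: int = 40,
    n_frames: int = 12_000,
    mode: str = "OT",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, map and pair ``n_sessions`` independent recordings.

    Map centres are drawn uniformly over the stimulation area eroded by
    the recording range in degrees, so every insertion's units can have
    their RFs inside the stimulated area.  Returns ``(units, pairs)``
    tables pooled over sessions.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mode = mode.upper()
    geom = probe.default_probe()
    rr = population.RECORDING_RANGE_UM[mode]
    g = population.GRADIENT_OT if mode == "OT" else population.GRADIENT_LGN
    half = np.array(STIM_EXTENT_DEG) / 2 - rr * g
    unit_tables = []
    pair_tables = []
    for s in range(n_sessions):
        center = rng.uniform(-half, half)
        stim = stimulus.generate_checkerboard(n_frames, rng=rng)
        pop = population.build_population(
            units_per_session, mode=mode, jitter_sigma=jitter_sigma,
            geometry=geom, rng=rng, map_center_deg=tuple(center),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flagged out-of-area units expected
            spk = simulate.simulate_spikes(pop, stim, rng=rng, geometry=geom)
        from .io import Recording  # local import to avoid h5py at module load

        rec = Recording(stim, geom, spk, pop)
        units = rfmap.map_session(rec, mode=mode, session_id=f"s{s}")
        units["true_az"] = pop.rf_center_deg[:, 0]
        units["true_el"] = pop.rf_center_deg[:, 1]
        units["true_polarity"] = pop.polarity
        units["true_size_deg"] = pop.rf_size_deg
        unit_tables.append(units)
        pair_tables.append(pairs_mod.enumerate_pairs(units, geom))
    units = pd.concat(unit_tables, ignore_index=True)
    pairs = (
        pd.concat(pair_tables, ignore_index=True)
        if pair_tables
        else pd.DataFrame()
    )
    return units, pairs
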