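"""Shared fixtures.

Expensive simulations (the default jitter sweep, the RF-recovery cohort,
the multi-session synthetic study) are session-scoped so that property
tests and the acceptance checks share one computation.
"""

import warnings

import numpy as np
import pytest

from retinotract import experiment, jitter, population, probe, simulate, stimulus


@pytest.fixture(scope="session")
def default_sweep():
    """Full-scale jitter sweep at the default grid and trial counts."""
    cfg = jitter.JitterConfig(seed=20_250_101)
    curve = jitter.sweep_sigma(cfg)
    return cfg, curve


@pytest.fixture(scope="session")
def recovery_cohort():
    """20 well-driven units with >= 1,000 spikes each, plus their truth.

    Zero map jitter, so fitted parameters can be compared against the
    generator's ground truth directly.
    """
    rng = np.random.default_rng(424_242)
    geom = probe.default_probe()
    stim = stimulus.generate_checkerboard(15_000, rng=rng)
    pop = population.build_population(20, "OT", 0.0, geom, rng=rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spk = simulate.simulate_spikes(pop, stim, rng=rng, geometry=geom)
    return stim, pop, spk


@pytest.fixture(scope="session")
def synthetic_study():
    """Multi-session OT study at known jitter sigma = 0.10."""
    sigma_true = 0.10
    units, pairs = experiment.run_synthetic_study(
        sigma_true, n_sessions=10, units_per_session=35, n_frames=15_000,
        seed=777,
    )
    return sigma_true, units, pairs


@pytest.fixture()
def small_stim():
    return stimulus.generate_checkerboard(600, seed=5)
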