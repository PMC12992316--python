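"""Pipeline configuration: TOML loading, defaults and per-stage seeds."""

from __future__ import annotations

import copy
import hashlib
import tomllib
from pathlib import Path
from typing import Any

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "outdir": "results/pipeline",
    "log_level": "INFO",
    "synthetic": {
        "mode": "OT",
        "n_units": 60,
        "jitter_sigma": 0.13,
        "duration_s": 300.0,
        "baseline_rate_hz": 0.5,
        "gain_hz": 20.0,
    },
    "rf_mapping": {
        "p_threshold": 1e-5,
        "size_threshold_deg": 15.0,
    },
    "pairs": {},
    "mc": {
        "reps": 1000,
    },
    "jitter": {
        "sigma_max": 0.5,
        "sigma_step": 0.05,
        "trials_per_sigma": 39_000,
        "tau_axons": 2_000,
        "tau_repeats": 20,
        "geometry": "disk2d",
        # nearby-pair median RF distance measured in the optic tract
        "measured_median_deg": 21.3,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Defaults, optionally overridden by a TOML file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path, "rb") as f:
        user = tomllib.load(f)
    return _merge(DEFAULT_CONFIG, user)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from (global seed, stage name).

    Stable across processes and Python versions (sha256-based), so any
    stage can be rerun in isolation and reproduce the pipeline's result.
    """
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)
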