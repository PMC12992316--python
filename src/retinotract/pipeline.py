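"""End-to-end orchestration: simulate -> map -> pairs -> models -> report."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io, jitter, mc, pairs as pairs_mod, population, probe, rfmap, simulate, stimulus
from .config import load_config, stage_seed

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_simulate(cfg: dict, outdir: Path) -> Path:
    c = cfg["synthetic"]
    seed = stage_seed(cfg["seed"], "simulate")
    rng = np.random.default_rng(seed)
    geom = probe.default_probe()
    n_frames = int(round(c["duration_s"] * stimulus.DEFAULT_FRAME_RATE))
    stim = stimulus.generate_checkerboard(n_frames, rng=rng)
    pop = population.build_population(
        c["n_units"], mode=c["mode"], jitter_sigma=c["jitter_sigma"],
        geometry=geom, rng=rng,
        baseline_rate_hz=c["baseline_rate_hz"], gain_hz=c["gain_hz"],
    )
    spk = simulate.simulate_spikes(pop, stim, rng=rng, geometry=geom)
    path = outdir / "recording.h5"
    io.save_recording(path, io.Recording(stim, geom, spk, pop))
    logger.info("simulate: %d units, %d frames -> %s", pop.n_units, n_frames, path)
    return path


def run_map_rf(cfg: dict, outdir: Path) -> Path:
    rec_path = outdir / "recording.h5"
    if not rec_path.exists():
        raise PipelineError(f"map-rf stage: missing upstream file {rec_path}")
    rec = io.load_recording(rec_path)
    c = cfg["rf_mapping"]
    units = rfmap.map_session(
        rec, p_threshold=c["p_threshold"],
        size_threshold_deg=c["size_threshold_deg"],
    )
    path = outdir / "units.csv"
    units.to_csv(path, index=False)
    logger.info("map-rf: %d/%d units passed QC -> %s",
                int(units["passed_qc"].sum()), len(units), path)
    return path


def run_pairs(cfg: dict, outdir: Path) -> Path:
    units_path = outdir / "units.csv"
    rec_path = outdir / "recording.h5"
    for p in (units_path, rec_path):
        if not p.exists():
            raise PipelineError(f"pairs stage: missing upstream file {p}")
    units = pd.read_csv(units_path)
    geom = io.load_recording(rec_path).probe
    pair_df = pairs_mod.enumerate_pairs(units, geom)
    if len(pair_df) == 0:
        raise PipelineError(
            "pairs stage: no pairs could be formed (fewer than two "
            "QC-passed units in every session)"
        )
    pair_df.to_csv(outdir / "pairs.csv", index=False)
    try:
        summary = pairs_mod.compare_groups(pair_df).to_dict()
    except ValueError as e:
        raise PipelineError(f"pairs stage: {e}") from e
    _write_json(outdir / "pair_summary.json", summary)
    logger.info("pairs: %d pairs (%d nearby)", len(pair_df), summary["n_nearby"])
    return outdir / "pair_summary.json"


def run_mc(cfg: dict, outdir: Path) -> dict[str, dict]:
    reps = cfg["mc"]["reps"]
    out = {}
    for preset in ("ot", "lgn"):
        seed = stage_seed(cfg["seed"], f"mc-{preset}")
        pred = mc.predict_rf_distance(mc.MCConfig.preset(preset, reps=reps, seed=seed))
        out[preset] = pred.to_dict()
        _write_json(outdir / f"mc_{preset}.json", out[preset])
    logger.info("mc-predict: OT median %.2f deg, LGN median %.2f deg",
                out["ot"]["median_deg"], out["lgn"]["median_deg"])
    return out


def run_jitter_fit(cfg: dict, outdir: Path) -> dict:
    c = cfg["jitter"]
    n_steps = int(round(c["sigma_max"] / c["sigma_step"])) + 1
    jcfg = jitter.JitterConfig(
        sigma_grid=np.round(np.arange(n_steps) * c["sigma_step"], 10),
        trials_per_sigma=c["trials_per_sigma"],
        tau_axons=c["tau_axons"],
        tau_repeats=c["tau_repeats"],
        geometry=c["geometry"],
        seed=stage_seed(cfg["seed"], "jitter"),
    )
    curve = jitter.sweep_sigma(jcfg)
    curve.to_csv(outdir / "jitter_curve.csv", index=False)
    est = jitter.estimate_retinotopy(c["measured_median_deg"], curve, jcfg)
    _write_json(outdir / "retinotopy.json", est.to_dict())
    logger.info("jitter-fit: sigma*=%.3f tau*=%.2f", est.sigma_star, est.tau_star)
    return est.to_dict()


def run_pipeline(config: dict | str | Path | None = None) -> dict[str, Any]:
    """Execute all stages; returns the aggregated report (also on disk).

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    run_simulate(cfg, outdir)
    run_map_rf(cfg, outdir)
    run_pairs(cfg, outdir)
    mc_out = run_mc(cfg, outdir)
    est = run_jitter_fit(cfg, outdir)
    summary = json.loads((outdir / "pair_summary.json").read_text())
    report = {
        "seed": cfg["seed"],
        "synthetic": cfg["synthetic"],
        "pairs": summary,
        "mc_ot_median_deg": mc_out["ot"]["median_deg"],
        "mc_ot_ci95_deg": [mc_out["ot"]["ci95_low_deg"], mc_out["ot"]["ci95_high_deg"]],
        "mc_lgn_median_deg": mc_out["lgn"]["median_deg"],
        "mc_lgn_ci95_deg": [mc_out["lgn"]["ci95_low_deg"], mc_out["lgn"]["ci95_high_deg"]],
        "sigma_star": est["sigma_star"],
        "tau_star": est["tau_star"],
        "deviation_deg": est["deviation_deg"],
        "displacement_um": est["displacement_um"],
    }
    _write_json(outdir / "report.json", report)
    return report
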