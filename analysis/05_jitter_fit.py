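#!/usr/bin/env python
"""Estimate the degree of retinotopy in the optic tract.

Simulates nearby-pair RF distances under Gaussian RF-position jitter
(sigma = 0 to 0.5 in steps of 0.05, where sigma = 1 spans the 135-deg
represented field / 300-um tract width), quantifies spatial monotonicity
with Kendall's tau, and intersects the simulated median-vs-sigma curve
with the measured optic-tract nearby-pair median (21.3 deg).  Writes
results/analysis/jitter_curve.csv and retinotopy.json.
"""

import argparse
import logging
from pathlib import Path

from retinotract import pipeline
from retinotract.config import load_config

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = load_config()
    cfg["seed"] = args.seed
    OUTDIR.mkdir(parents=True, exist_ok=True)
    est = pipeline.run_jitter_fit(cfg, OUTDIR)
    print(
        f"measured median {est['measured_median_deg']:.1f} deg intersects the "
        f"simulated curve at sigma* = {est['sigma_star']:.3f} "
        f"(Kendall's tau* = {est['tau_star']:.2f})"
    )
    print(
        f"equivalently: RF locations deviate ~{est['deviation_deg']:.0f} deg "
        f"from an ideal retinotopic map, i.e. axons are displaced "
        f"~{est['displacement_um']:.0f} um within the tract — moderate, not "
        "fine-grained, retinotopy"
    )


if __name__ == "__main__":
    main()
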