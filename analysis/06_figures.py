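#!/usr/bin/env python
"""Render the summary figures for the analysis outputs.

Produces: RF-distance vs electrode-distance scatter, nearby/distant
distance distributions with the Monte Carlo overlay, the median-vs-sigma
and tau-vs-sigma curves with the fitted intersection, and colour-coded
ideal vs jittered topographic maps.  Writes PNGs under
results/analysis/figures/.
"""

import argparse
from pathlib import Path

from retinotract.figures import make_figures

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    for p in make_figures(OUTDIR):
        print(p)


if __name__ == "__main__":
    main()
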