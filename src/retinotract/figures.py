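"""Summary figures for a completed pipeline run."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .jitter import JitterConfig
from .stimulus import STIM_EXTENT_DEG


def _maybe(path: Path, what: str):
    if not path.exists():
        warnings.warn(f"{what} not found ({path}); plot skipped", stacklevel=3)
        return None
    return path


def plot_pair_scatter(pairs_csv: Path, out: Path) -> bool:
    """RF distance vs electrode distance over all pairs."""
    if _maybe(pairs_csv, "pair table") is None:
        return False
    df = pd.read_csv(pairs_csv)
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    jitter_x = np.random.default_rng(0).uniform(-3, 3, len(df))
    ax.scatter(df["electrode_distance_um"] + jitter_x, df["rf_distance_deg"],
               s=8, alpha=0.4, edgecolors="none")
    ax.set_xlabel("electrode distance (μm)")
    ax.set_ylabel("RF distance (deg)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return True


def plot_distance_distributions(
    pairs_csv: Path, mc_json: Path, out: Path
) -> bool:
    """Nearby / distant RF-distance histograms with the MC prediction."""
    if _maybe(pairs_csv, "pair table") is None:
        return False
    df = pd.read_csv(pairs_csv)
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    bins = np.linspace(0, max(df["rf_distance_deg"].max(), 1) * 1.05, 30)
    for label, color in (("nearby", "salmon"), ("distant", "firebrick")):
        d = df.loc[df["label"] == label, "rf_distance_deg"]
        if len(d):
            ax.hist(d, bins=bins, density=True, histtype="step",
                    color=color, label=f"{label} (n={len(d)})")
    if mc_json.exists():
        m = json.loads(mc_json.read_text())
        ax.axvline(m["median_deg"], color="gray", ls="--",
                   label=f"MC median {m['median_deg']:.1f}°")
    ax.set_xlabel("RF distance (deg)")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return True


def plot_sigma_curves(curve_csv: Path, retino_json: Path, out: Path) -> bool:
    """Median RF distance and Kendall's tau as functions of jitter sigma."""
    if _maybe(curve_csv, "jitter curve") is None:
        return False
    c = pd.read_csv(curve_csv)
    if len(c) == 0:
        warnings.warn("empty jitter curve; plot skipped", stacklevel=2)
        return False
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(7.4, 3.2))
    ax1.fill_between(c["sigma"], c["q25_deg"], c["q75_deg"], color="0.8")
    ax1.plot(c["sigma"], c["median_deg"], "k-")
    ax1.set_xlabel("jitter σ")
    ax1.set_ylabel("simulated RF distance (deg)")
    ax2.plot(c["sigma"], c["tau"], "k-")
    ax2.set_xlabel("jitter σ")
    ax2.set_ylabel("Kendall's τ")
    if retino_json.exists():
        est = json.loads(retino_json.read_text())
        ax1.axhline(est["measured_median_deg"], color="r", ls=":")
        ax1.axvline(est["sigma_star"], color="k", ls=":")
        ax2.axvline(est["sigma_star"], color="k", ls=":")
        ax2.axhline(est["tau_star"], color="r", ls=":")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return True


def plot_topographic_maps(out: Path, sigma: float = 0.13, seed: int = 0) -> bool:
    """Colour-coded ideal vs jittered topographic map of the tract.

    Points on a grid over the stimulation area are coloured by their
    ideal azimuth/elevation (hue/lightness); the right panel shows the
    same points after Gaussian RF jitter, visualising local scrambling
    with a preserved coarse gradient.
    """
    cfg = JitterConfig()
    rng = np.random.default_rng(seed)
    w, h = STIM_EXTENT_DEG
    nx, ny = 40, 24
    gx, gy = np.meshgrid(np.linspace(-w / 2, w / 2, nx),
                         np.linspace(-h / 2, h / 2, ny))
    pos = np.c_[gx.ravel(), gy.ravel()]
    colors = np.c_[
        (pos[:, 0] + w / 2) / w, 0.3 + 0.5 * (pos[:, 1] + h / 2) / h,
        1 - (pos[:, 0] + w / 2) / w,
    ]
    jittered = pos + sigma * cfg.field_span_deg * rng.standard_normal(pos.shape)
    fig, axes = plt.subplots(1, 2, figsize=(7.4, 2.8), sharex=True, sharey=True)
    for ax, pts, title in (
        (axes[0], pos, "ideal retinotopy (σ = 0)"),
        (axes[1], jittered, f"σ = {sigma:g}"),
    ):
        ax.scatter(pts[:, 0], pts[:, 1], c=colors, s=8, edgecolors="none")
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("azimuth (deg)")
    axes[0].set_ylabel("elevation (deg)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return True


def make_figures(outdir: str | Path, figdir: str | Path | None = None) -> list[Path]:
    """Produce all available figures for a pipeline output directory."""
    outdir = Path(outdir)
    figdir = Path(figdir) if figdir is not None else outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    made = []
    if plot_pair_scatter(outdir / "pairs.csv", figdir / "rf_vs_electrode.png"):
        made.append(figdir / "rf_vs_electrode.png")
    if plot_distance_distributions(
        outdir / "pairs.csv", outdir / "mc_ot.json",
        figdir / "distance_distributions.png",
    ):
        made.append(figdir / "distance_distributions.png")
    if plot_sigma_curves(
        outdir / "jitter_curve.csv", outdir / "retinotopy.json",
        figdir / "sigma_curves.png",
    ):
        made.append(figdir / "sigma_curves.png")
    retino = outdir / "retinotopy.json"
    sigma = 0.13
    if retino.exists():
        sigma = json.loads(retino.read_text())["sigma_star"]
    if plot_topographic_maps(figdir / "topographic_maps.png", sigma=sigma):
        made.append(figdir / "topographic_maps.png")
    return made
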