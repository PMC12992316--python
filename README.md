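# retinotract

Tools for asking how precisely a bundle of visual axons preserves the map
of visual space — *retinotopy* — at the scale of a multielectrode
recording.

In retinotopically organised tissue, neighbouring neurons have
neighbouring receptive fields (RFs), so two single units isolated on the
same recording site should have RF centres only a few degrees apart.
`retinotract` implements the full analysis chain needed to test this in
the mouse optic tract (OT) and its retinorecipient control, the lateral
geniculate nucleus (LGN):

1. **Synthetic recordings** — binary checkerboard movies (32×18 pixels,
   60 Hz, each frame exactly luminance-balanced) driving
   linear–nonlinear Poisson model units with known ground-truth RFs,
   positions on a simulated 4-shank probe, and a retinotopic
   position→RF map degraded by controllable Gaussian jitter.
2. **RF mapping** — spike-triggered averaging over a 500 ms window
   (Δt = 1/60 s, 30 lags), voxel significance against the N(0, 1/C)
   null (detection gate *p* < 10⁻⁵ at any voxel), SVD separation into
   spatial and temporal filters, elliptical 2D-Gaussian fits, polarity
   and peak-latency classification, and quality control including the
   15° size exclusion for wide-field axons in OT sessions.
3. **Pair statistics** — nearby pairs (largest waveforms on the same
   recording site) vs distant pairs, summarised as median ± MAD with a
   Mann–Whitney U-test and Pearson correlation of RF distance against
   electrode distance.
4. **Baseline Monte Carlo model** — the RF distance expected for nearby
   pairs *if* the tissue were perfectly retinotopic: two points uniform
   in a ball of radius *r* (the single-unit recording range), separation
   *D* > *d* (an exclusion for the physical size of the neurons), RF
   distance *D·g* for a retinotopy gradient *g* (deg/μm); 1,000 × *n*
   draws give the predicted median and the 95 % CI of the median of a
   sample of size *n*.
5. **Degree-of-retinotopy estimation** — nearby-pair RF distances are
   simulated under Gaussian RF-position jitter σ (σ = 1 spans the 135°
   represented field, equivalently the 300 μm tract width), spatial
   monotonicity is quantified by Kendall's τ, and the measured median is
   intersected with the simulated median-vs-σ curve to obtain
   (σ\*, τ\*) and the equivalent RF deviation (σ\*·135°) and axonal
   displacement (σ\*·300 μm).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (outputs under `results/analysis/`):

```bash
python analysis/01_simulate_recording.py    # demo OT session, sigma = 0.13
python analysis/02_map_receptive_fields.py
python analysis/03_pair_statistics.py
python analysis/04_mc_baseline.py
python analysis/05_jitter_fit.py
python analysis/06_figures.py
```

which prints (seed 1):

```
36/60 units passed QC
  ON: n=21, RF size median 4.5 deg, peak latency median 50 ms
  OFF: n=15, RF size median 3.7 deg, peak latency median 50 ms
nearby pairs: n=39, RF distance 27.1 +/- 10.1 deg (median +/- MAD)
distant pairs: n=591, RF distance 24.3 +/- 9.4 deg
Mann-Whitney U-test (two-sided): p = 0.492
Pearson R (RF vs electrode distance) = 0.02 (p = 0.694)
LGN: predicted nearby-pair RF distance median 4.6 deg (95% CI of the median [4.2, 4.9] deg)
optic tract: predicted nearby-pair RF distance median 9.3 deg (95% CI of the median [7.9, 10.8] deg)
measured median 21.3 deg intersects the simulated curve at sigma* = 0.122 (Kendall's tau* = 0.52)
equivalently: RF locations deviate ~16 deg from an ideal retinotopic map, i.e. axons are
displaced ~37 um within the tract — moderate, not fine-grained, retinotopy
```

Read bottom-up: a recording simulated with moderate RF jitter shows *no*
nearby-vs-distant RF-distance difference (U-test p ≈ 0.5, R ≈ 0), even
though a perfectly retinotopic tract would put nearby-pair RFs only
~9.3° apart.  A measured nearby-pair median of 21.3° is therefore
incompatible with strict local retinotopy and corresponds to a moderate
map (τ ≈ 0.5) in which axons sit ~40 μm away from their ideal position.

The same stages are available as a single executable
(`retinotract run-all --config configs/demo.toml`, plus per-stage
subcommands `simulate`, `map-rf`, `pairs`, `mc-predict`, `jitter-fit`,
`figures`).

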