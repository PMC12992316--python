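# Methods

This note documents the models implemented in `retinotract`, the
assumptions behind them, the parameters that matter, and the places
where a design had to be chosen among several defensible options.

## Stimulus

The RF-mapping stimulus is a 32×18-pixel binary checkerboard covering
73° of azimuth by 44° of elevation (pixels ≈ 2.28° × 2.44°), refreshed
at 60 Hz.  Each frame is an independent random permutation of a fixed
vector of 288 white (+1) and 288 black (−1) pixels: this satisfies the
constant-luminance constraint *exactly* (every frame sums to zero) while
keeping every pixel's marginal distribution balanced and frames
independent across time.  The per-frame balance induces a small negative
covariance between pixels within a frame (−1/575), which is negligible
for all analyses here but is the reason calibration tests compare
against exact binomial tails rather than assuming strict independence.
Coordinates are centred: azimuth ∈ [−36.5°, 36.5°], elevation ∈
[−22°, 22°].

## Synthetic units and what they emulate

Units are linear–nonlinear Poisson (LN) neurons with separable
spatiotemporal RFs:

* **Spatial profile** — elliptical 2D Gaussian; the RF *size* statistic
  is the mean of the long- and short-axis diameters at 1 σ
  (σ_long + σ_short).  Sizes are drawn log-normally around the measured
  medians (OT: 3.6° ON / 3.5° OFF; LGN: 4.7° ON / 4.3° OFF) with
  MAD-matched spread; log-normal keeps the support positive.
* **Temporal kernel** — biphasic (Gaussian lobe at the peak latency,
  weaker opposite lobe ~55 ms later), unit L2 norm, 30 lags at 1/60 s.
  Peak latencies are drawn log-normally around the measured medians
  (46–51 ms by class).
* **Encoding** — drive = spatiotemporal filter applied to the stimulus
  history, normalised so a fully covered RF gives unit-variance drive;
  rate = baseline + gain × max(drive, 0); spike counts per frame are
  Poisson and spike times uniform within their frame.  The encoding
  model is not constrained by any measurement (only linear RFs are ever
  analysed), so the simplest LN-Poisson model consistent with linear STA
  recovery is used, with defaults baseline 0.5 Hz and gain 20 Hz per
  drive s.d. (≈ 8.5 spikes/s mean driven rate — a realistic sustained
  rate under white-noise stimulation and enough spikes in a 5-min
  presentation for clean SVD separation; both are configurable).
  Crucially, the drive is normalised by the norm of the *untruncated*
  Gaussian: a unit whose RF centre lies outside the stimulated area is
  driven only by its (vanishing) tail and fires near baseline, as such a
  unit would in a real recording — it is flagged, not renormalised into
  an artificial edge-responder.

**Probe and unit placement.**  The default probe has 4 shanks × 8 sites
(200 μm shank pitch, 25 μm site pitch).  In the optic tract the fibres
run along the bundle axis, so the represented position depends only on
the cross-section: shanks are laid out along the tract axis (where a
600-μm shank span physically cannot fit inside the 300-μm cross-section)
and sites along the vertical cross-sectional axis.  OT units are uniform
in a 300-μm-diameter cylinder; LGN units in a box spanning the probe.
Two additional constraints emulate what a real session can yield:
units must lie within the single-unit recording range of at least one
site (20 μm OT, 40 μm LGN — extracellular amplitude falls as 1/distance
and isolation fails beyond that), and their ideal RF centre must fall
inside the stimulated area (an RF off the screen cannot be mapped).
Both are configurable and can be disabled.

**Retinotopic map and jitter.**  The ideal RF centre is an affine image
of position: map centre + g·(x, y) with g = 135°/300 μm = 0.45°/μm in
the OT, and g = 0.11°/μm along the probe-sampled axes (shank spread,
site spread) in the LGN — a nucleus has no invariant axis, so the
gradient is aligned with the plane the probe actually samples.  The map
centre is the visual-field location represented at the insertion point;
multi-session studies draw it uniformly over the stimulated area (eroded
by the recording range in degrees), emulating independent probe
placements across animals.  Gaussian jitter with per-axis s.d.
σ × 135° is then added to each unit's RF centre; σ is the same
dimensionless jitter used by the degraded-retinotopy model below, so
generator and estimator speak the same language.

## RF mapping

Per unit: the spike-triggered average (STA) over a 500 ms window at
Δt = 1/60 s (30 lags); spikes in the first 500 ms (incomplete history)
are discarded rather than zero-padded.  Voxelwise two-sided p-values are
computed against the null that STA voxels are N(0, 1/C), C the spike
count; the detection gate is p < 10⁻⁵ at any voxel, with no
multiple-comparison correction (the raw threshold is the method's
definition).  Gated STAs are separated into rank-1 spatial × temporal
factors by SVD (space–time separability assumed); the temporal kernel is
unit-norm and the spatial filter carries the amplitude and the sign of
the STA's largest-magnitude voxel, so OFF units have a negative spatial
peak and a positive temporal peak.  An elliptical 2D Gaussian with free
offset is fitted to the signed spatial filter by bounded least squares
in degree coordinates, initialised at the extremum pixel with σ₀ = 1
pixel and σ bounded to (0.1, 20) pixels; non-convergence flags the unit
rather than dropping it silently.  Polarity is the sign of the spatial
extremum, peak latency the lag of the temporal extremum × Δt.

Quality control requires, in addition to the detection gate:

* **a single, distinct, localized feature** — at the dominant lag, the
  4-connected component of significant pixels (p < 10⁻⁵) containing the
  peak must hold ≥ 80 % of all significant pixels;
* **a fit that describes the feature** — the fitted centre must lie
  within two pixels of the STA's largest-magnitude voxel (a least-squares
  optimum that wandered off the detected blob describes noise, not the
  RF) and inside the stimulated area (a centre beyond the mapped region
  is extrapolation from a clipped RF);
* **OT only:** RF size < 15°, excluding wide-field axons.  The 15°
  threshold is applied to the 1σ-diameter-mean size because that is the
  only size statistic defined.

With ≥ ~2,000 spikes per unit these steps recover simulated RF centres
with a median error of ≈ 0.1 pixel and polarity with 100 % accuracy
(verified in the test suite).  Below ~1,000 spikes the first singular
component of the 30 × 576 STA can be captured by the noise floor for the
smallest (sub-pixel) RFs; the consistency gates above then reject such
units instead of letting them contaminate pair statistics.

## Pair analysis

All unordered pairs of QC-passed units are formed within a session
(simultaneity), never across sessions; pairs are pooled across sessions
for group statistics, as measured datasets pool across animals.  Nearby
pairs have their largest waveforms on the same recording site (zero
electrode distance); electrode distance is the 3D distance between
dominant sites.  RF distance is the Euclidean distance between fitted
Gaussian centres in (azimuth, elevation), treating the stimulus plane as
flat.  Groups are summarised as median ± MAD (unscaled), compared with a
two-sided Mann–Whitney U-test (exact for small tie-free samples, normal
approximation with tie correction otherwise), and the Pearson
correlation of RF distance vs electrode distance is reported both over
all pairs and over distant pairs only, because it is ambiguous whether
the zero-distance nearby pairs belong in that scatter.

## Baseline Monte Carlo model

Parameters: recording range r (μm), exclusion threshold d (μm),
retinotopy gradient g (deg/μm), empirical sample size n.  Two points are
drawn uniformly in the ball of radius r (direction uniform on the
sphere, radius ∝ U^{1/3}); pairs with separation D ≤ d are redrawn
(rejection, not truncation — an eliminated trial is simply repeated);
the RF distance is D·g.  The procedure runs 1,000 × n times; the point
estimate is the pooled median (the median of the 1,000 per-replicate
medians is also exposed and differs negligibly), and the 95 % CI of the
median of a sample of size n is the 2.5/97.5 percentile interval of the
per-replicate medians — the only reading consistent with "1,000 × n
repeats" plus a CI "of sample size n".  Presets: OT r = 20 μm,
d = 2 μm (axon calibre), g = 0.45°/μm, n = 39; LGN r = 40 μm, d = 10 μm
(cell-body size), g = 0.11°/μm, n = 150.  The sampler is validated
against closed forms: mean separation 36r/35 and CDF
s³/r³ − 9s⁴/(16r⁴) + s⁶/(32r⁶) at d = 0.

## Degraded-retinotopy (jitter) model

For each σ on the grid (0 to 0.5 in steps of 0.05): a probe position is
drawn in the stimulation area, two ideal RF positions are drawn within
the recording range around it, independent per-axis Gaussian noise with
s.d. σ × 135° is added to each, and the trial is eliminated if either
jittered RF falls outside the 73° × 44° area.  Per σ, 39,000 accepted
trials give the median and quartiles of the RF distance.  Design choices
where the construction was genuinely open:

* **Pair geometry** — pairs are sampled directly in the 2D visual plane
  (each point uniform in the disk of radius r·g = 9° around the probe),
  because jitter and stimulation-area clipping are intrinsically 2D
  quantities; the sampling radius is the recording range r = 20 μm (the
  2-μm exclusion alone would make pairs essentially coincident and could
  not produce the model's own ~9° baseline), and the d·g exclusion is
  retained by redrawing closer pairs.  At σ = 0 the disk geometry gives
  a median ≈ 13 % below the 3D ball model (8.1° vs 9.3°) — an expected
  and documented geometric difference; a `ball3d` variant (pair drawn in
  the physical ball, cross-sectional components projected to the visual
  plane) is available behind a flag.
* **Probe domain** — probe positions are drawn from the stimulation
  area eroded by r·g per side, so ideal RFs always lie inside the area
  and trials are eliminated only *because of the added jitter*; σ = 0
  therefore has exactly zero rejections.
* **Kendall's τ** — per σ, 2,000 ideal RF positions are drawn uniformly
  over the stimulation area, jittered, and τ is computed between ideal
  and jittered coordinates separately per axis; the two axis values are
  averaged and the procedure repeated 20 times.  τ(0) = 1 exactly and
  τ → 0 for noise-dominated maps.  This construction is an
  interpretation (the population, area and axis treatment admit
  variants); it is cross-checked against Greiner's relation
  τ = (2/π)·asin(ρ) with ρ² = Var(position)/(Var(position) + σ²·135²)
  per axis, which gives τ ≈ 0.48 at σ = 0.13.
* **Jitter target** — noise is added to RF positions only, not to the
  physical probe or axon positions.
* **Estimation** — σ\* is found by linear interpolation of the
  median-vs-σ curve at the measured median (the 0.05 grid is coarse
  relative to the estimates of interest, so interpolation is implied);
  τ\* by interpolating the τ-vs-σ curve at σ\*.  A measured median
  outside the simulated range raises an error reporting the bracketing
  values.  The conversions deviation = σ\*·135° and displacement =
  σ\*·300 μm are exact identities.  Rejected trials are excluded from
  the distance statistics but counted and reported.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the measured datasets —
balanced white-noise stimulation, separable RFs with measured size and
latency statistics, inverse-distance amplitudes, dominant-site pairing,
session-level probe placement — so that passing tests demonstrate the
analysis chain is correct and internally consistent (e.g. a known jitter
σ fed through simulation → mapping → pairing → estimation is recovered
to ±0.05).  It does not model spike-sorting errors, overlapping
waveforms, eye movements, behavioural state, non-Poisson firing,
nonlinear or non-separable RFs, or non-RGC axons beyond the wide-field
size exclusion; agreement on synthetic data therefore does not certify
those aspects of real recordings.  Measured quantities printed in the
literature (nearby-pair medians 4.8°/21.3°, R = 0.42, etc.) enter only
as fixed inputs to the estimation stage — they cannot be re-derived
without the raw recordings.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.Generator`; pipeline stages
derive their seeds from the global seed by SHA-256 of
`"{seed}:{stage}"`, so any stage can be rerun in isolation and
identically seeded runs produce byte-identical outputs (HDF5 written
with `track_times=False`).  Default problem sizes — 5-min demo sessions,
1,000 × n Monte Carlo draws, 39,000 trials and 20 × 2,000-point τ
evaluations per σ, 10-session × 35-unit recovery studies at 15,000
frames — were chosen so each stage completes in seconds to a few
minutes on a single core while keeping Monte Carlo error well inside the
tolerances quoted above; all are configurable.  Degenerate inputs are
handled explicitly: empty populations halt the pipeline at the pairs
stage with a stage-named error, zero-variance correlations are reported
as undefined rather than NaN, all-zero STAs refuse separation, and
unit–site distances are clamped at 1 μm in the amplitude model.

## Known limitations

The τ construction and the 2D pair geometry are interpretations of an
under-specified procedure; the estimator is validated by
self-consistency and end-to-end recovery rather than against an
external reference implementation.  The Gaussian-fit error for RFs much
smaller than a stimulus pixel is dominated by pixelisation.  The LGN
mode aligns the retinotopy gradient with the probe plane; real LGN maps
have curvature and anisotropy that are not modelled.
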