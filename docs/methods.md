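# Methods

This note documents the models, detection rules, parameter choices and known
limitations of the larvahomeo pipelines, and what the synthetic generators do
and do not emulate.

## Optical quantal analysis

**Model.** A stimulus trial is a short image sequence: baseline frames, then
post-stimulus frames. A release site that releases on a trial contributes a
fluorescence transient — a 2-D Gaussian of width `psf_sigma` — whose ΔF image
(mean post-stimulus − mean baseline) is the detection substrate. Release is
Bernoulli per site per trial; Pr is the fraction of analysed trials with at
least one detected spot center within the site's capture radius.
Multi-vesicular release within one site and trial still scores a single
event, because Pr is defined per trial; centers assigned to no site are kept
and still count toward quantal density, which is site-agnostic.

**Detection.** ΔF images are matched against a zero-mean, unit-norm template
averaged from seed spots. Pixels whose normalized cross-correlation reaches
`corr_threshold` (default 0.5) form participating-pixel regions
(8-connectivity); regions of ≥ `min_pixels` (default 4) pixels yield one
center each, the ΔF-intensity-weighted centroid (subpixel; a local-maximum
alternative is available via `use_local_maxima`). Correlation within one
template radius of the image border is discarded: zero padding makes it
unreliable there. The pipeline default of `smooth_sigma = 0.5` px Gaussian
smoothing before ΔF computation was chosen by an ROC sweep on synthetic
stacks at event SNR 5 (amplitude / noise SD = 5): it gives precision and
recall ≥ 0.95 with the default threshold and region size, whereas unsmoothed
matching under-segments and heavier smoothing correlates the noise and
floods the threshold. All three knobs are exposed in config.

**QC.** Trials are excluded for motion (registration shift of the trial's
baseline image against the median baseline above `motion_limit`), focus loss
(Laplacian-variance drop beyond `focus_drop_limit` of the median), or
stimulus failure (whole-ROI ΔF maximum below `response_floor`, only when a
floor is supplied). Exclusions carry reasons and are written to the run log;
nothing is dropped silently.

**Units.** Coordinates are 0-based pixel indices with x = column,
y = row; areas use `pixel_size²` (μm²/px). Quantal density is
events · stimulus⁻¹ · μm⁻². The number of trials is always a parameter —
typical protocols use 100–200 stimuli at 0.1 Hz — and never hard-coded.

## Crawling kinematics

**Path smoothing.** Successive centroids within 1 mm of a running cluster
seed and within 2 s of its first timestamp merge into one center-of-mass
node (greedy forward pass — single-pass and order-deterministic; the merge
rule needs an algorithm and this is the simplest one consistent with it).
Stride lengths are distances between consecutive nodes; velocity is total
node-path length over recording duration. The first and last half-cluster
are truncated by construction, a negligible bias for recordings much longer
than the merge window.

**Curvature.** Each midline is rotated into its principal-axis frame and a
third-degree polynomial v(u) is fitted; κ = |v″|/(1 + v′²)^{3/2} is
evaluated along the fit, trimming 10% of the span at each end where a cubic
is unconstrained. The per-frame scalar is max |κ| over the body — the most
sensitive reduction for head sweeps; mean |κ| is available via config. On
sampled circles the fitted max-κ matches 1/r within 2% for arcs up to
~0.5 rad; the cubic graph fit systematically overestimates peak curvature as
the arc grows (≈ 4% at 0.8 rad), and for strongly C-shaped postures the
value is a monotone proxy rather than a metric curvature. This does not
affect event detection, which uses a within-recording quantile threshold.

**Reorientations and phases.** A reorientation is a maximal run of frames
with curvature above the recording's 75th percentile lasting ≥ 500 ms;
single-frame sub-threshold dips do not split a run; event duration counts
n_frames / frame_rate, so at 10 Hz a 600 ms exceedance is one event and a
400 ms exceedance is none. Events truncated by the recording boundary count
if they meet the duration rule within the recording. Stops — unstated in
the original rule set and therefore a declared choice here — are runs of
smoothed speed < 0.1 mm/s lasting ≥ 2 s between events; the remainder is
crawl, and the three phase types tile the recording exactly. Turning angles
are unsigned angles in [0°, 180°] between least-squares headings of the
crawl phases flanking a single reorientation, oriented by travel direction.

## ΔF/F bouts and peristaltic waves

**Normalisation.** dff = (F − Fm − F0)/F0 with Fm the mean of a synapse-free
background region (this also cancels bleaching shared by ROI and
background) and F0 a low quantile — default the 8th percentile — of the
background-subtracted ROI trace. A quantile baseline is robust to the
unknown fraction of time the preparation is active; the quantile is
configurable and recorded in output metadata. Adding a constant to the raw
fluorescence leaves bout detection unchanged because F0 is recomputed.

**Bouts.** A bout starts when dff strictly exceeds the threshold (default
0.10 — "10% of baseline" measured in ΔF/F units is 0.10) and ends when it
falls back below; sub-threshold gaps shorter than `merge_gap` (0.15 s) merge
adjacent runs, and candidates shorter than `min_duration` (0.25 s) are
discarded. These two hysteresis values suppress single-frame noise
crossings at 20 Hz; both are configurable and written to output metadata.
Onset is the first supra-threshold frame time and offset one frame period
after the last, so duration = n_frames × frame period; the integral is the
trapezoidal integral of dff over the bout.

**Waves.** Bouts in adjacent segments whose onsets lie within
`max_onset_gap` (default 1.0 s) chain into a wave; a wave must span every
segment with strictly monotone onsets. Direction is P→A when the posterior
segment leads. Non-monotone and incomplete chains are returned with
reasons, never silently dropped, and partial waves at recording boundaries
are excluded from rates. Delays are onset-to-onset in wave order; overlap
is the pairwise intersection of bout intervals. Rates (bouts and waves per
10 min, fraction time active) normalise to a 600 s window and refuse
recordings shorter than 60 s.

**Registration.** Translation is estimated per frame against a reference —
by default the frame with maximal total (ROI) intensity, i.e. one in which
all NMJs are active and visible — using upsampled cross-correlation.
Plain cross-correlation (not phase-whitened) is used because whitening
amplifies high-frequency interpolation error on resampled noisy frames;
on structured NMJ-like images integer shifts are recovered exactly and
0.5 px shifts to < 0.02 px. An optional affine stage refines each frame by
least squares on a 6-parameter transform. A hook accepts a nonlinear
(diffeomorphic) refiner for strong contraction-induced shape change; the
default is none, and translation + affine suffice for the synthetic
validation surface. Contraction displacement is the maximum norm of the
within-bout translation relative to the pre-bout frame, in μm.

## Line-profile FWHM

The model is offset + A·exp(−(x−c)²/2σ²), fitted by least squares with
moment initialisation (offset = min, amplitude = max − min, center and σ =
intensity-weighted mean and SD) — reliable for unimodal profiles. Fits are
rejected on non-convergence or σ exceeding the sampled span. FWHM is
reported as 2.355 σ, the conventional rounding of 2√(2 ln 2) = 2.3548…;
the numerical half-maximum width of the fitted curve agrees with it to
0.03%. Averaging re-centers each profile on the sample nearest its fitted
peak (true peak samples are sensitive to local maxima) and assigns samples
to the nearest point of a fixed grid — 42.5 nm steps within ±0.4 μm —
without interpolation; mean and SEM are per grid point, with SEM reported
as 0 when a single profile contributes (n = 1 flagged). Nearest-sample
assignment distorts the mean curve when the acquisition grid differs from
the averaging grid by a non-integer factor; with matched grids (the
default protocol) it is lossless. Two-channel profiles are fitted
independently; channel separation is reported but not modelled. SEM is
computed across profiles, with provenance columns so a per-animal
aggregation can be applied downstream.

## Synthetic generators

The generators produce the statistical structure each stage assumes, not
photorealistic data:

- **Quantal episodes** — Bernoulli release per site per trial; transient
  with single-frame rise and geometric decay (factor 0.65/frame), a fast
  indicator's shape without modelling binding kinetics; i.i.d. Gaussian
  pixel noise (not Poisson shot noise — sufficient for recovery testing and
  with simpler oracle math); static resting NMJ fluorescence with per-site
  brightness variation plus a smooth background texture, so frames have the
  spatial structure that registration-based QC needs and no translational
  symmetry. Sites closer than one PSF width trigger a warning, not an error.
  Defaults: 10 frames/episode, 3 baseline frames, 48×48 px at 0.2 μm/px,
  event SNR 5. Noise statistics and event amplitudes of real recordings are
  not published, so these are declared, realistic choices — not calibrated.
- **Crawl sessions** — scheduled crawl / reorient / stop phases. Crawl
  advances along the heading with arc length v(t − (T/2π)·sin 2πt/T): speed
  pulses at the stride period T and averages exactly to v. Crawl and stop
  curvature is a smooth stride-locked |sin| waveform, so its exceedances of
  any within-distribution threshold last ~1 frame, keeping the
  75th-percentile / 500 ms rule separable by construction; reorient
  curvature is drawn at 0.8–1.2 × the reorient scale (20× the crawl scale).
  Midlines are circular arcs of the frame's true curvature scaled to the
  body length, so the midline-fitting path is exercised against known κ.
  Heading changes by ±`heading_change_per_reorient` at each reorientation.
- **Peristaltic trains** — waves arrive as a refractory Poisson process
  (refractory = full bout span including intersegmental stagger) so truth
  bouts cannot merge unintentionally; any overlap that does occur is
  flagged in the truth table. Bouts are trapezoids (linear rise, plateau,
  linear fall) of total duration `bout_duration × duration_scale`; the
  `duration_scale` knob reproduces the prolonged-bout / unchanged-delay
  phenotype pattern of synaptically weakened animals for validation.
- **Line profiles** — the closed-form Gaussian on the protocol grid plus
  i.i.d. noise, with optional center jitter emulating imperfect line
  placement.

Passing recovery tests on these generators shows the measurement chain is
correct under its stated assumptions; it does not certify performance on
real movies with non-Gaussian noise, drifting focus, occlusions, or
multi-larva scenes, which remain the user's QC responsibility.

## Validation problem sizes

The recovery checks run at desk scale, chosen so the full suite completes in
seconds while the statistics remain decisive: release-probability recovery
uses 20 seeded runs of 200 trials on 48×48 px stacks with four sites ≥ 6
PSF widths apart; behavior segmentation uses ten ~100 s sessions at 10 Hz;
bout dissociation uses three 600 s three-segment recordings at 20 Hz per
condition; profile FWHM uses 50 profiles at 5% noise. Estimated Pr is
compared against the central 99% binomial interval of the true Pr computed
from the binomial CDF (for n = 200, p = 0.5 this is [82, 118] events).

## Known limitations

- Pr conflates detection failures with release failures when SNR drops well
  below the validated regime (amplitude/noise ≥ 5 after smoothing).
- The curvature scalar is fit-based and saturates for strongly C-shaped
  postures; comparisons should stay within one protocol.
- Wave assembly assumes one bout per segment per wave; doublet bursts within
  a segment chain to the nearest onset and may reject the wave as
  non-monotone (reported, not dropped).
- The affine registration stage is a local optimiser initialised from the
  translation stage; very large deformations need the nonlinear hook.
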