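# larvahomeo

Measurement pipelines for *Drosophila* larval neuromuscular physiology and
behavior: optical quantal analysis of nerve-evoked transmission, crawling
kinematics of freely moving larvae, in vivo ΔF/F bout and peristaltic-wave
analysis, and Gaussian line-profile FWHM fitting for super-resolution synapse
images. Every stage ships with a seeded synthetic-data generator that
produces inputs with known ground truth, so the whole chain is validated by
parameter recovery at desk scale.

## Who this is for

Labs measuring synaptic transmission and locomotor behavior in the larval
motor system — with a postsynaptically targeted calcium indicator
(SynapGCaMP6f-style) at the NMJ, centroid tracking of crawling larvae, or
line profiles across immunostained synaptic puncta — who want the standard
analysis steps as tested, scriptable components rather than ad hoc notebooks.

## What it computes

**Quantal imaging** (`larvahomeo.quantal`). Episodic stimulation stacks
(10 frames/episode, 3–4 baseline frames) are smoothed, QC-filtered
(motion, focus, failed stimuli), and turned into per-trial ΔF images
(mean post-stimulus − mean baseline). Transmission events appear as ΔF
spots detected by normalized cross-correlation against a template built from
seed spots; spot centers accumulate into a release-probability map. Per-site

    Pr = (trials with ≥ 1 spot center at the site) / (trials analysed)

and quantal density = spot centers / (trials × imaged area, μm²) — the
optical analogue of quantal content.

**Behavior** (`larvahomeo.behavior`). Centroid tracks at 10 Hz are smoothed
by merging centroids within 1 mm over 2 s windows into center-of-mass nodes;
stride lengths are distances between successive nodes, velocity is total
path length / recording duration. Body curvature comes from a cubic
polynomial fitted to the midline in its principal-axis frame,
κ = |v″| / (1 + v′²)^{3/2}; a reorientation event is a run of frames with
curvature above the recording's 75th percentile lasting ≥ 500 ms. Phases
(crawl / reorient / stop) tile the recording, and turning angles are
measured between the headings of crawl phases flanking one reorientation.

**ΔF/F bouts and waves** (`larvahomeo.bouts`). Continuous 20 Hz recordings
are registered (translation, optional affine; subpixel cross-correlation),
background-subtracted (dff = (F − Fm − F0)/F0) and segmented into bouts:
dF/F surpassing 10% of baseline starts a bout, falling below ends it. Bouts
across adjacent segments chain into peristaltic waves with direction (P→A
or A→P), intersegmental onset delay, and pairwise overlap; derived metrics
include fraction time active, bouts and waves per 10 min, contraction
displacement from registration translations, and relative bout
amplitude/duration in successive 10 min bins.

**Line profiles** (`larvahomeo.profiles`). Each ~1 μm profile is fitted with
offset + A·exp(−(x−c)²/2σ²); profiles are re-centered on the sample nearest
the fitted peak, averaged on a ±0.4 μm grid at 42.5 nm steps, a second
Gaussian is fitted to the mean curve and

    FWHM = 2.355 × σ.

**Synthetic data** (`larvahomeo.synthetic`). Binomially releasing sites
convolved with a PSF blob plus noise; alternating crawl / head-sweep
trajectories with arc midlines; refractory-Poisson peristaltic bout trains
with controlled duration, delay and direction; noisy Gaussian profiles.
All seeded, all returning ground truth.

## Worked example

```
$ larvahomeo simulate peristalsis --seed 7 --out sim
wrote 19 waves across 3 segments to sim
$ larvahomeo bouts --traces sim/traces.csv --out run
57 bouts, 19 waves (0 chains rejected)
```

The generator placed 19 peristaltic waves in a 10 min three-segment
recording; the analysis recovered one bout per segment per wave (57 bouts)
and chained all 19 waves with consistent P→A direction. `run/waves.csv`
holds per-wave onset, mean intersegmental delay (~0.3 s, the generator's
setting) and mean overlap; `run/bouts.csv` the per-bout durations and
amplitudes.

```
$ larvahomeo simulate profile --seed 7 --out prof_sim
wrote 50 line profiles to prof_sim
$ larvahomeo profile --profiles prof_sim/profiles.csv --out prof_fit
final FWHM 0.2817 um from 50 profiles
```

Fifty noisy profiles of a σ = 0.12 μm punctum average to a final FWHM of
0.2817 μm, within 0.3% of the generating 2.355 × 0.12 = 0.2826 μm.

Other entry points: `larvahomeo simulate quantal|crawl`, `larvahomeo
quantal`, `larvahomeo behavior`, `larvahomeo compare` (rank-sum comparison
of a metric between two result tables). Every run writes its resolved
config and a file manifest next to its outputs; identical seed + config
gives byte-identical tables.

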