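"""In vivo dF/F trace analysis: registration, bouts, and peristaltic waves.

Continuous recordings of a postsynaptic calcium indicator at the larval NMJ
(or cytosolic indicator in premotor interneurons) show bouts of evoked
activity riding on a baseline.  A bout starts when dF/F surpasses 10% of
baseline and ends when it falls back below.  Bouts in adjacent body segments
chain into peristaltic waves whose direction (posterior-to-anterior or the
reverse), intersegmental onset delay, and bout overlap are the core readouts
of locomotor wave dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.registration import phase_cross_correlation

__all__ = [
    "FluorTrace",
    "Bout",
    "WaveEvent",
    "RegistrationResult",
    "BinnedTimeCourse",
    "register_frames",
    "extract_trace",
    "detect_bouts",
    "bout_metrics",
    "fraction_time_active",
    "assemble_waves",
    "contraction_displacement",
    "pmsi_activity",
    "binned_timecourse",
]


@dataclass
class FluorTrace:
    """Background-subtracted, baseline-normalised fluorescence time series.

    dff = (F - Fm - F0) / F0 where Fm is the spatially uniform muscle /
    background fluorescence and F0 the baseline of the background-subtracted
    ROI signal.
    """

    t: np.ndarray  # s, uniform
    dff: np.ndarray
    roi_id: str = ""
    f0: float | None = None
    fm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.t.shape != self.dff.shape:
            raise ValueError("t and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff must be finite everywhere")
        dt = np.diff(self.t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("t must be uniformly sampled")

    @property
    def frame_period(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(len(self.t) * self.frame_period)


@dataclass
class Bout:
    """One supra-threshold activity bout with its summary metrics."""

    onset: float  # s
    offset: float  # s (time dff falls back below threshold)
    peak_time: float
    peak_amplitude: float
    mean_amplitude: float
    integral: float  # dF/F * s, trapezoidal

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def time_to_max(self) -> float:
        return self.peak_time - self.onset


@dataclass
class WaveEvent:
    """A chain of bouts across adjacent segments forming one peristaltic wave."""

    member_bouts: dict[str, Bout]  # segment label -> bout
    direction: str  # "P->A" or "A->P"
    onset_delays: list[float]  # s, onset-to-onset in wave order
    overlap_times: list[float]  # s, per adjacent pair

    @property
    def onset(self) -> float:
        return min(b.onset for b in self.member_bouts.values())


@dataclass
class RegistrationResult:
    """Per-frame rigid/affine transforms against a reference frame."""

    translations: np.ndarray  # n x 2 (dy, dx) px
    reference_frame: int
    residuals: np.ndarray  # per-frame correlation score
    unregistered: np.ndarray  # bool flags
    affine: list[np.ndarray] | None = None  # optional per-frame 2x3 matrices


@dataclass
class BinnedTimeCourse:
    """Per-bin bout statistics relative to a reference bin."""

    bin_edges: np.ndarray  # s
    relative_amplitude: np.ndarray
    relative_duration: np.ndarray
    reference_bin: int
    n_bouts: np.ndarray


# ---------------------------------------------------------------------------


def _affine_refine(frame: np.ndarray, reference: np.ndarray, init_shift) -> np.ndarray:
    """Refine a translation to a full 2x3 affine by least squares on intensity."""
    from scipy import ndimage, optimize

    def residual(p):
        mat = np.array([[1 + p[0], p[1]], [p[2], 1 + p[3]]])
        off = np.array([p[4], p[5]])
        warped = ndimage.affine_transform(frame, mat, offset=off, order=1)
        return (warped - reference).ravel()

    x0 = np.array([0.0, 0.0, 0.0, 0.0, -init_shift[0], -init_shift[1]])
    sol = optimize.least_squares(residual, x0, method="lm", max_nfev=50)
    p = sol.x
    return np.array([[1 + p[0], p[1], p[4]], [p[2], 1 + p[3], p[5]]])


def register_frames(
    stack: np.ndarray,
    reference: str | int = "high-intensity",
    stages: Sequence[str] = ("translation",),
    roi_mask: np.ndarray | None = None,
    upsample_factor: int = 20,
    correlation_floor: float = 0.2,
    nonlinear_refiner: Callable | None = None,
) -> RegistrationResult:
    """Register every frame of a movie to a reference frame.

    The translation stage maximises the 2-D cross-correlation (subpixel via
    upsampled phase correlation); an optional affine stage refines each frame
    by intensity-based least squares.  ``reference='high-intensity'`` picks
    the frame with maximal total (ROI) intensity, the standard choice for a
    frame in which all NMJs are active and visible.  A ``nonlinear_refiner``
    hook accepts (frame, reference) and may apply a diffeomorphic refinement;
    the default is none.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be frames x H x W with >= 2 frames")
    for s in stages:
        if s not in ("translation", "affine"):
            raise ValueError(f"unknown registration stage {s!r}")
    if reference == "high-intensity":
        sums = (
            stack[:, roi_mask].sum(axis=1) if roi_mask is not None else stack.sum(axis=(1, 2))
        )
        ref_idx = int(np.argmax(sums))
    else:
        ref_idx = int(reference)
    ref = stack[ref_idx]

    n = stack.shape[0]
    translations = np.zeros((n, 2))
    residuals = np.ones(n)
    affines: list[np.ndarray] | None = [] if "affine" in stages else None
    for i in range(n):
        if i == ref_idx:
            if affines is not None:
                affines.append(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
            continue
        shift, error, _ = phase_cross_correlation(
            ref, stack[i], upsample_factor=upsample_factor, normalization=None
        )
        translations[i] = shift
        residuals[i] = 1.0 - error
        if affines is not None:
            affines.append(_affine_refine(stack[i], ref, shift))
        if nonlinear_refiner is not None:
            nonlinear_refiner(stack[i], ref)
    if affines is not None and len(affines) < n:
        affines.insert(ref_idx, np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
    unregistered = residuals < correlation_floor
    return RegistrationResult(
        translations=translations,
        reference_frame=ref_idx,
        residuals=residuals,
        unregistered=unregistered,
        affine=affines,
    )


def extract_trace(
    stack: np.ndarray,
    roi_mask: np.ndarray,
    background_mask: np.ndarray,
    frame_rate: float = 20.0,
    roi_id: str = "",
    baseline_quantile: float = 0.08,
) -> FluorTrace:
    """dF/F trace from ROI and synapse-free background masks.

    F(t) is the ROI mean, Fm(t) the background mean; F0 is a low quantile
    (default 8th percentile) of F - Fm over the recording, a robust baseline
    when the preparation is active for an unknown fraction of the time.
    Subtracting Fm also cancels any bleaching shared by ROI and background.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not roi_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if (roi_mask & background_mask).any():
        raise ValueError("roi and background masks must be disjoint")
    F = stack[:, roi_mask].mean(axis=1)
    Fm = stack[:, background_mask].mean(axis=1)
    corrected = F - Fm
    f0 = float(np.quantile(corrected, baseline_quantile))
    if f0 <= 0:
        raise ValueError("baseline F0 <= 0: trace cannot be normalised")
    t = np.arange(stack.shape[0]) / frame_rate
    return FluorTrace(t=t, dff=(corrected - f0) / f0, roi_id=roi_id, f0=f0, fm=Fm)


def detect_bouts(
    trace: FluorTrace,
    threshold: float = 0.10,
    min_duration: float = 0.25,
    merge_gap: float = 0.15,
) -> list[Bout]:
    """Threshold-crossing bout detection with hysteresis.

    A bout starts when dF/F surpasses ``threshold`` (strictly greater, so a
    peak of exactly 0.09 against the default 0.10 is sub-threshold) and ends
    when it falls back below.  Supra-threshold runs separated by gaps shorter
    than ``merge_gap`` merge; candidates shorter than ``min_duration`` are
    discarded.  Onset is the time of the first supra-threshold frame; offset
    is one frame period after the last, so duration = n_frames * frame period.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dt = trace.frame_period
    above = trace.dff > threshold
    runs: list[tuple[int, int]] = []  # [start, end] inclusive frame indices
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs across short sub-threshold gaps
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1] - 1) * dt < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    bouts = []
    for s, e in merged:
        if (e - s + 1) * dt < min_duration - 1e-9:
            continue
        seg = trace.dff[s : e + 1]
        k = int(np.argmax(seg))
        bouts.append(
            Bout(
                onset=float(trace.t[s]),
                offset=float(trace.t[e] + dt),
                peak_time=float(trace.t[s + k]),
                peak_amplitude=float(seg[k]),
                mean_amplitude=float(seg.mean()),
                integral=float(np.trapezoid(seg, dx=dt)),
            )
        )
    return bouts


def fraction_time_active(bouts: list[Bout], trace: FluorTrace) -> float:
    """Total bout time divided by recording length, in [0, 1]."""
    total = sum(b.duration for b in bouts)
    return min(total / trace.duration, 1.0)


def bout_metrics(bouts: list[Bout], trace: FluorTrace):
    """Tidy per-bout metric table plus the fraction of time active."""
    import pandas as pd

    rows = [
        {
            "roi_id": trace.roi_id,
            "onset_s": b.onset,
            "offset_s": b.offset,
            "duration_s": b.duration,
            "time_to_max_s": b.time_to_max,
            "peak_dff": b.peak_amplitude,
            "mean_dff": b.mean_amplitude,
            "integral_dff_s": b.integral,
        }
        for b in bouts
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "roi_id",
            "onset_s",
            "offset_s",
            "duration_s",
            "time_to_max_s",
            "peak_dff",
            "mean_dff",
            "integral_dff_s",
        ],
    )
    return table, fraction_time_active(bouts, trace)


def _overlap(a: Bout, b: Bout) -> float:
    return max(0.0, min(a.offset, b.offset) - max(a.onset, b.onset))


def assemble_waves(
    bouts_by_segment: dict[str, list[Bout]],
    max_onset_gap: float = 1.0,
    segment_order: list[str] | None = None,
) -> tuple[list[WaveEvent], list[dict]]:
    """Chain bouts across adjacent segments into peristaltic waves.

    ``segment_order`` lists segments from anterior to posterior (default: the
    dict's key order).  Starting from each unused bout in the segment where a
    wave could begin, the chain extends to the adjacent segment's nearest
    unused bout with onset within ``max_onset_gap``.  Chains spanning every
    segment with strictly monotone onsets become waves — direction "P->A"
    when onsets decrease along the anterior-to-posterior axis (the posterior
    segment leads) — with onset-to-onset delays and pairwise overlaps in wave
    order.  Non-monotone or incomplete chains are rejected with a reason and
    returned separately, never silently dropped.
    """
    order = list(bouts_by_segment) if segment_order is None else list(segment_order)
    if len(order) < 2:
        raise ValueError("need >= 2 segments")
    used: dict[str, set[int]] = {seg: set() for seg in order}
    waves: list[WaveEvent] = []
    rejected: list[dict] = []

    # candidate chains seeded from every bout of the first segment in `order`;
    # extension walks toward the last segment picking the nearest-onset bout.
    seed_seg = order[0]
    for i0, b0 in enumerate(bouts_by_segment.get(seed_seg, [])):
        if i0 in used[seed_seg]:
            continue
        chain: list[tuple[str, int, Bout]] = [(seed_seg, i0, b0)]
        ok = True
        for seg in order[1:]:
            prev_onset = chain[-1][2].onset
            candidates = [
                (abs(b.onset - prev_onset), j, b)
                for j, b in enumerate(bouts_by_segment.get(seg, []))
                if j not in used[seg] and abs(b.onset - prev_onset) <= max_onset_gap
            ]
            if not candidates:
                ok = False
                rejected.append(
                    {
                        "reason": "incomplete",
                        "segments": [c[0] for c in chain],
                        "onsets": [c[2].onset for c in chain],
                    }
                )
                break
            _, j, b = min(candidates)
            chain.append((seg, j, b))
        if not ok:
            continue
        onsets = np.array([c[2].onset for c in chain])
        diffs = np.diff(onsets)
        if np.all(diffs < 0):
            direction = "P->A"  # posterior leads: onsets decrease A->P ordering
        elif np.all(diffs > 0):
            direction = "A->P"
        else:
            rejected.append(
                {
                    "reason": "non-monotone",
                    "segments": [c[0] for c in chain],
                    "onsets": list(onsets),
                }
            )
            continue
        for seg, j, _ in chain:
            used[seg].add(j)
        # report delays/overlaps in wave (temporal) order
        ordered = chain if direction == "A->P" else chain[::-1]
        delays = [
            float(ordered[k + 1][2].onset - ordered[k][2].onset)
            for k in range(len(ordered) - 1)
        ]
        overlaps = [
            _overlap(ordered[k][2], ordered[k + 1][2]) for k in range(len(ordered) - 1)
        ]
        waves.append(
            WaveEvent(
                member_bouts={seg: b for seg, _, b in chain},
                direction=direction,
                onset_delays=delays,
                overlap_times=overlaps,
            )
        )
    waves.sort(key=lambda w: w.onset)
    return waves, rejected


def contraction_displacement(
    reg: RegistrationResult,
    bouts: list[Bout],
    frame_rate: float,
    pixel_size: float,
) -> list[float]:
    """Peak NMJ displacement (um) during each bout.

    Displacement is the maximum Euclidean norm of the per-frame registration
    translation within the bout window, relative to the position just before
    bout onset.  Bouts containing unregistered frames are reported as NaN.
    """
    out = []
    n = len(reg.translations)
    for b in bouts:
        i0 = max(int(np.floor(b.onset * frame_rate)), 0)
        i1 = min(int(np.ceil(b.offset * frame_rate)), n)
        if i1 <= i0:
            out.append(0.0)
            continue
        if reg.unregistered[i0:i1].any():
            warnings.warn("unregistered frames inside bout; displacement unreliable", stacklevel=2)
            out.append(float("nan"))
            continue
        pre = reg.translations[max(i0 - 1, 0)]
        disp = np.hypot(*(reg.translations[i0:i1] - pre).T)
        out.append(float(disp.max() * pixel_size))
    return out


def pmsi_activity(
    traces: dict[str, FluorTrace],
    threshold: float = 0.10,
    min_duration: float = 0.25,
    merge_gap: float = 0.15,
    max_onset_gap: float = 1.0,
    segment_order: list[str] | None = None,
) -> dict[str, float]:
    """Premotor-interneuron activity metrics normalised to a 10 min window.

    Returns bouts per 10 min (mean over segment ROIs), complete waves per
    10 min, and fraction time active (mean over ROIs).
    """
    if not traces:
        raise ValueError("no traces supplied")
    any_trace = next(iter(traces.values()))
    if any_trace.duration < 60.0:
        raise ValueError("recording shorter than 60 s: rates unstable")
    scale = 600.0 / any_trace.duration
    bouts_by_segment = {
        seg: detect_bouts(tr, threshold, min_duration, merge_gap) for seg, tr in traces.items()
    }
    waves, _ = assemble_waves(bouts_by_segment, max_onset_gap, segment_order)
    n_bouts = np.mean([len(b) for b in bouts_by_segment.values()])
    fta = np.mean(
        [fraction_time_active(bouts_by_segment[seg], traces[seg]) for seg in traces]
    )
    return {
        "bouts_per_10min": float(n_bouts * scale),
        "waves_per_10min": float(len(waves) * scale),
        "fraction_time_active": float(fta),
    }


def binned_timecourse(
    bouts: list[Bout],
    recording_length: float,
    bin_length: float = 600.0,
    reference_bin: int = 0,
) -> BinnedTimeCourse:
    """Mean bout amplitude and duration per time bin, relative to a reference
    bin — the readout for acute perturbations applied mid-recording."""
    n_bins = int(np.floor(recording_length / bin_length + 1e-9))
    if n_bins < 2:
        raise ValueError("recording must span at least two bins")
    edges = bin_length * np.arange(n_bins + 1)
    amp = np.full(n_bins, np.nan)
    dur = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        sel = [b for b in bouts if edges[k] <= b.onset < edges[k + 1]]
        counts[k] = len(sel)
        if sel:
            amp[k] = np.mean([b.mean_amplitude for b in sel])
            dur[k] = np.mean([b.duration for b in sel])
    if counts[reference_bin] == 0:
        raise ValueError("reference bin contains no bouts")
    return BinnedTimeCourse(
        bin_edges=edges,
        relative_amplitude=amp / amp[reference_bin],
        relative_duration=dur / dur[reference_bin],
        reference_bin=reference_bin,
        n_bouts=counts,
    )
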