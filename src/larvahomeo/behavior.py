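"""Locomotion analytics for freely crawling larvae.

Larval crawling alternates between an active crawling phase (peristaltic
forward motion on a roughly straight trajectory) and reorientation phases in
which the animal holds position and sweeps its head, producing high body
curvature.  This module tracks the centroid, smooths the path by
center-of-mass merging, measures stride lengths and velocity, scores per-frame
midline curvature from a cubic polynomial fit, detects reorientation events by
the 75th-percentile curvature rule with a 500 ms minimum duration, tiles the
recording into crawl / reorient / stop phases, and measures turning angles
between successive crawl phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LarvaTrack",
    "SmoothedPath",
    "CurvatureSeries",
    "PhaseSegmentation",
    "KinematicsSummary",
    "track_centroids",
    "smooth_track",
    "stride_lengths",
    "fit_midline_curvature",
    "detect_reorientations",
    "segment_phases",
    "turning_angles",
    "summarize_kinematics",
    "binned_distance",
]


@dataclass
class LarvaTrack:
    """Timestamped centroid track, optionally with per-frame midlines (mm)."""

    t: np.ndarray  # s
    centroid: np.ndarray  # n x 2, mm
    frame_rate: float  # Hz
    midline: list[np.ndarray] | None = None  # per frame: k x 2 points, mm
    arena_diameter: float | None = None  # mm
    flagged_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.midline is not None:
            for m in self.midline:
                if len(m) < 4:
                    raise ValueError("midlines need >= 4 points per frame")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.frame_rate


@dataclass
class SmoothedPath:
    """Center-of-mass nodes from merging nearby centroids in space and time."""

    nodes_t: np.ndarray  # s
    nodes_xy: np.ndarray  # n x 2 mm
    merge_radius: float = 1.0  # mm
    merge_window: float = 2.0  # s

    @property
    def path_length(self) -> float:
        if len(self.nodes_xy) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(self.nodes_xy, axis=0).T)))


@dataclass
class CurvatureSeries:
    """Scalar body curvature per frame and its 75th percentile."""

    t: np.ndarray  # s
    kappa: np.ndarray  # mm^-1; NaN where the midline was degenerate
    quantile75: float = field(init=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        valid = self.kappa[np.isfinite(self.kappa)]
        if np.any(valid < 0):
            raise ValueError("kappa must be non-negative")
        self.quantile75 = float(np.percentile(valid, 75)) if valid.size else float("nan")


@dataclass
class PhaseSegmentation:
    """Ordered (label, t_start, t_end) phases tiling the recording."""

    phases: list[tuple[str, float, float]]
    reorient_min_duration: float = 0.5  # s

    def durations(self, label: str) -> list[float]:
        return [t1 - t0 for lab, t0, t1 in self.phases if lab == label]

    def frame_labels(self, t: np.ndarray) -> np.ndarray:
        """Label every frame time by the phase containing it."""
        out = np.empty(len(t), dtype=object)
        for lab, t0, t1 in self.phases:
            out[(t >= t0 - 1e-9) & (t < t1 - 1e-9)] = lab
        if len(t) and out[-1] is None:
            out[-1] = self.phases[-1][0]
        return out


@dataclass
class KinematicsSummary:
    """Per-larva kinematic summary (one row per animal)."""

    velocity: float  # mm/s
    stride_lengths: list[float]
    reorient_durations: list[float]
    crawl_durations: list[float]
    stop_durations: list[float]
    turning_angles: list[float]  # degrees, [0, 180]

    def to_dict(self) -> dict[str, float]:
        def _mean(v):
            return float(np.mean(v)) if len(v) else float("nan")

        return {
            "velocity_mm_per_s": self.velocity,
            "mean_stride_length_mm": _mean(self.stride_lengths),
            "mean_reorient_duration_s": _mean(self.reorient_durations),
            "mean_crawl_duration_s": _mean(self.crawl_durations),
            "mean_turning_angle_deg": _mean(self.turning_angles),
            "n_reorientations": float(len(self.reorient_durations)),
        }


# ---------------------------------------------------------------------------


def track_centroids(
    movie_or_table,
    frame_rate: float = 10.0,
    pixel_size: float | None = None,
    threshold: float | None = None,
    max_flagged_fraction: float = 0.10,
) -> LarvaTrack:
    """2-D centroid tracking from a movie array, or pass-through of a table.

    A movie (frames x H x W) is thresholded per frame (fixed ``threshold`` or
    Otsu when None), the largest connected foreground component is kept and
    its centroid converted to mm with ``pixel_size``.  Frames with no
    foreground carry the previous centroid forward and are flagged; more than
    ``max_flagged_fraction`` flagged frames is an error.  A DataFrame with
    columns ``t_s, x_mm, y_mm`` passes through after validation.
    """
    import pandas as pd

    if isinstance(movie_or_table, pd.DataFrame):
        table = movie_or_table
        required = {"t_s", "x_mm", "y_mm"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        t = table["t_s"].to_numpy(dtype=float)
        xy = table[["x_mm", "y_mm"]].to_numpy(dtype=float)
        return LarvaTrack(t=t, centroid=xy, frame_rate=frame_rate)

    movie = np.asarray(movie_or_table)
    if movie.ndim != 3 or movie.shape[0] == 0:
        raise ValueError("movie must be a non-empty frames x H x W array")
    if pixel_size is None:
        raise ValueError("pixel_size is required for movie input")
    centroids = np.full((movie.shape[0], 2), np.nan)
    flagged = np.zeros(movie.shape[0], dtype=bool)
    for i, frame in enumerate(movie):
        if threshold is None:
            from skimage.filters import threshold_otsu

            thr = threshold_otsu(frame) if frame.max() > frame.min() else np.inf
        else:
            thr = threshold
        fg = frame > thr
        if not fg.any():
            flagged[i] = True
            centroids[i] = centroids[i - 1] if i else (np.nan, np.nan)
            continue
        labels, n = ndimage.label(fg)
        largest = np.argmax(ndimage.sum_labels(fg, labels, index=range(1, n + 1))) + 1
        r, c = ndimage.center_of_mass(fg, labels, largest)
        centroids[i] = (c * pixel_size, r * pixel_size)
    if flagged[0] and not flagged.all():
        first_good = np.flatnonzero(~flagged)[0]
        centroids[:first_good] = centroids[first_good]
    if flagged.mean() > max_flagged_fraction:
        raise ValueError(
            f"{flagged.mean():.0%} of frames have no foreground object"
        )
    t = np.arange(movie.shape[0]) / frame_rate
    return LarvaTrack(t=t, centroid=centroids, frame_rate=frame_rate, flagged_frames=flagged)


def smooth_track(
    track: LarvaTrack, merge_radius: float = 1.0, merge_window: float = 2.0
) -> SmoothedPath:
    """Merge centroids within ``merge_radius`` mm over a ``merge_window`` s
    window into single center-of-mass nodes (greedy forward pass)."""
    if len(track.t) == 0:
        raise ValueError("empty track")
    nodes_t, nodes_xy = [], []
    seed_xy = track.centroid[0]
    seed_t = track.t[0]
    members = [0]
    for i in range(1, len(track.t)):
        d = np.hypot(*(track.centroid[i] - seed_xy))
        if d <= merge_radius and (track.t[i] - seed_t) <= merge_window:
            members.append(i)
        else:
            nodes_t.append(track.t[members].mean())
            nodes_xy.append(track.centroid[members].mean(axis=0))
            seed_xy = track.centroid[i]
            seed_t = track.t[i]
            members = [i]
    nodes_t.append(track.t[members].mean())
    nodes_xy.append(track.centroid[members].mean(axis=0))
    return SmoothedPath(
        nodes_t=np.asarray(nodes_t),
        nodes_xy=np.asarray(nodes_xy),
        merge_radius=merge_radius,
        merge_window=merge_window,
    )


def stride_lengths(path: SmoothedPath) -> list[float]:
    """Euclidean distances between consecutive center-of-mass nodes (mm)."""
    if len(path.nodes_xy) < 2:
        return []
    return list(np.hypot(*np.diff(path.nodes_xy, axis=0).T))


def _frame_curvature(points: np.ndarray, reduce: str, edge_trim: float) -> float:
    """Max (or mean) |kappa| of a cubic polynomial fit to one midline."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0):
        return np.nan
    # principal axis as abscissa
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u = centered @ vt[0]
    v = centered @ vt[1]
    if np.ptp(u) == 0:
        return np.nan
    coeffs = np.polyfit(u, v, 3)
    p = np.poly1d(coeffs)
    # evaluate away from the fit ends, where a cubic's curvature is unconstrained
    lo, hi = u.min(), u.max()
    span = hi - lo
    xs = np.linspace(lo + edge_trim * span, hi - edge_trim * span, 200)
    d1 = p.deriv(1)(xs)
    d2 = p.deriv(2)(xs)
    kappa = np.abs(d2) / (1 + d1**2) ** 1.5
    return float(kappa.max() if reduce == "max" else kappa.mean())


def fit_midline_curvature(
    midlines: list[np.ndarray],
    t: np.ndarray | None = None,
    frame_rate: float = 10.0,
    reduce: str = "max",
    edge_trim: float = 0.1,
) -> CurvatureSeries:
    """Scalar body curvature per frame from cubic midline fits.

    Each midline is rotated into its principal-axis frame, a third-degree
    polynomial v(u) is fitted, and kappa = |v''| / (1 + v'^2)^(3/2) is
    evaluated along the fit (trimming ``edge_trim`` of the span at each end
    where the cubic is unconstrained).  The per-frame scalar is max |kappa|
    (``reduce='mean'`` available).  Degenerate midlines give NaN and are
    excluded from the percentile.
    """
    if reduce not in ("max", "mean"):
        raise ValueError("reduce must be 'max' or 'mean'")
    kappa = np.empty(len(midlines))
    for i, m in enumerate(midlines):
        if len(m) < 4:
            raise ValueError("midlines need >= 4 points")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            kappa[i] = _frame_curvature(m, reduce, edge_trim)
    if t is None:
        t = np.arange(len(midlines)) / frame_rate
    return CurvatureSeries(t=np.asarray(t, dtype=float), kappa=kappa)


def detect_reorientations(
    curv: CurvatureSeries,
    reorient_min_duration: float = 0.5,
    threshold: float | None = None,
) -> list[tuple[float, float]]:
    """Reorientation events: curvature above its 75th percentile for >= 500 ms.

    Maximal runs of supra-threshold frames become events; a sub-threshold gap
    of a single frame does not split a run.  Event duration is counted as
    n_frames / frame_rate; events shorter than ``reorient_min_duration`` are
    dropped.  Returns (t_start, t_end) pairs where t_end is the time the
    curvature falls back below threshold.
    """
    t, kappa = curv.t, curv.kappa
    if len(t) < 2:
        raise ValueError("need >= 2 s of data")
    dt = float(np.median(np.diff(t)))
    if (t[-1] - t[0]) + dt < 2.0:
        raise ValueError("need >= 2 s of data")
    thr = curv.quantile75 if threshold is None else threshold
    above = np.isfinite(kappa) & (kappa > thr)
    # bridge single-frame dips (gaps shorter than one frame period)
    bridged = above.copy()
    for i in range(1, len(above) - 1):
        if not above[i] and above[i - 1] and above[i + 1]:
            bridged[i] = True
    events = []
    i = 0
    n = len(bridged)
    while i < n:
        if bridged[i]:
            j = i
            while j + 1 < n and bridged[j + 1]:
                j += 1
            duration = (j - i + 1) * dt
            if duration >= reorient_min_duration - 1e-9:
                events.append((float(t[i]), float(t[i] + duration)))
            i = j + 1
        else:
            i += 1
    return events


def segment_phases(
    track: LarvaTrack,
    events: list[tuple[float, float]],
    stop_speed: float = 0.1,
    stop_min_duration: float = 2.0,
    speed_smooth_window: float = 0.5,
) -> PhaseSegmentation:
    """Tile the recording into reorient / stop / crawl phases.

    Reorient phases are the supplied events.  Within the remaining intervals,
    runs of smoothed centroid speed below ``stop_speed`` lasting at least
    ``stop_min_duration`` become stop phases; everything else is crawl.
    """
    for (s0, e0), (s1, _) in zip(events, events[1:]):
        if s1 < e0:
            raise ValueError("overlapping reorientation events")
    t = track.t
    dt = 1.0 / track.frame_rate
    t_end = float(t[-1] + dt)
    # smoothed frame-wise speed
    disp = np.hypot(*np.diff(track.centroid, axis=0).T) / np.diff(t)
    speed = np.concatenate([disp[:1], disp])
    win = max(1, int(round(speed_smooth_window * track.frame_rate)))
    speed = ndimage.uniform_filter1d(speed, size=win)

    labels = np.full(len(t), "crawl", dtype=object)
    for s, e in events:
        labels[(t >= s - 1e-9) & (t < e - 1e-9)] = "reorient"
    # stop runs inside non-reorient frames
    candidate = (labels != "reorient") & (speed < stop_speed)
    i = 0
    while i < len(t):
        if candidate[i]:
            j = i
            while j + 1 < len(t) and candidate[j + 1]:
                j += 1
            if (j - i + 1) * dt >= stop_min_duration - 1e-9:
                labels[i : j + 1] = "stop"
            i = j + 1
        else:
            i += 1
    # collapse per-frame labels into phases tiling [t0, t_end)
    phases: list[tuple[str, float, float]] = []
    start = float(t[0])
    for i in range(1, len(t)):
        if labels[i] != labels[i - 1]:
            phases.append((labels[i - 1], start, float(t[i])))
            start = float(t[i])
    phases.append((labels[-1], start, t_end))
    return PhaseSegmentation(phases=phases)


def _phase_heading(path: SmoothedPath, t0: float, t1: float) -> np.ndarray | None:
    sel = (path.nodes_t >= t0 - 1e-9) & (path.nodes_t < t1 + 1e-9)
    pts = path.nodes_xy[sel]
    if len(pts) < 2:
        return None
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    # orient by time: align with net displacement
    net = pts[-1] - pts[0]
    if np.dot(direction, net) < 0:
        direction = -direction
    return direction


def turning_angles(path: SmoothedPath, phases: PhaseSegmentation) -> list[float]:
    """Unsigned angle (degrees) between headings of crawl phases flanking a
    single reorientation.  Headings are least-squares line directions through
    each crawl phase's path nodes, oriented by travel direction."""
    seq = [p for p in phases.phases if p[0] in ("crawl", "reorient")]
    angles: list[float] = []
    for k in range(1, len(seq) - 1):
        lab, t0, t1 = seq[k]
        if lab != "reorient":
            continue
        before, after = seq[k - 1], seq[k + 1]
        if before[0] != "crawl" or after[0] != "crawl":
            continue
        h0 = _phase_heading(path, before[1], before[2])
        h1 = _phase_heading(path, after[1], after[2])
        if h0 is None or h1 is None:
            warnings.warn("crawl phase with < 2 path nodes skipped", stacklevel=2)
            continue
        cosang = np.clip(np.dot(h0, h1), -1.0, 1.0)
        angles.append(float(np.degrees(np.arccos(cosang))))
    return angles


def summarize_kinematics(
    path: SmoothedPath,
    phases: PhaseSegmentation,
    angles: list[float] | None = None,
) -> KinematicsSummary:
    """Collect per-larva kinematics: velocity = total path length / duration,
    stride list, per-phase duration lists and turning angles."""
    t0 = phases.phases[0][1]
    t1 = phases.phases[-1][2]
    duration = t1 - t0
    if duration <= 0:
        raise ValueError("zero-duration recording")
    if angles is None:
        angles = turning_angles(path, phases)
    return KinematicsSummary(
        velocity=path.path_length / duration,
        stride_lengths=stride_lengths(path),
        reorient_durations=phases.durations("reorient"),
        crawl_durations=phases.durations("crawl"),
        stop_durations=phases.durations("stop"),
        turning_angles=angles,
    )


def binned_distance(
    track: LarvaTrack, bin_length: float = 600.0, reference_bin: int = 0
) -> np.ndarray:
    """Path length per time bin relative to the reference bin."""
    t = track.t
    total_span = t[-1] - t[0] + 1.0 / track.frame_rate
    n_bins = int(np.floor(total_span / bin_length + 1e-9))
    if n_bins < 2:
        raise ValueError("recording must span at least two bins")
    seg = np.hypot(*np.diff(track.centroid, axis=0).T)
    seg_t = t[1:]  # distance attributed to the arriving frame
    edges = t[0] + bin_length * np.arange(n_bins + 1)
    dist = np.array(
        [seg[(seg_t > edges[k]) & (seg_t <= edges[k + 1])].sum() for k in range(n_bins)]
    )
    if dist[reference_bin] == 0:
        raise ValueError("reference bin has zero crawled distance")
    return dist / dist[reference_bin]
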