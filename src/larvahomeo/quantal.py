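"""Optical quantal analysis of episodic nerve-stimulation imaging.

Single-action-potential transmission events at individual synaptic release
sites appear as diffraction-limited dF spots in postsynaptic calcium-indicator
images.  Over a train of stimulus trials, counting per-site events yields the
release probability Pr = event trials / trials, and counting all spot centers
normalised by imaged area yields quantal density, the optical equivalent of
quantal content.

Pipeline: ``preprocess_stack`` -> ``qc_trials`` -> per-trial ``compute_delta_f``
-> ``detect_spots`` against a ``SpotTemplate`` -> ``build_pr_map`` /
``assign_sites_and_pr`` / ``quantal_density``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.measure import label as cc_label
from skimage.registration import phase_cross_correlation

__all__ = [
    "EpisodeStack",
    "SpotTemplate",
    "ReleaseSiteTable",
    "PrMap",
    "QuantalDensityResult",
    "preprocess_stack",
    "qc_trials",
    "compute_delta_f",
    "build_template",
    "detect_spots",
    "detect_spots_by_trial",
    "build_pr_map",
    "assign_sites_and_pr",
    "quantal_density",
]


@dataclass
class EpisodeStack:
    """Episodic stimulation imaging data: trials x frames x H x W.

    ``baseline_frames`` leading frames of every trial precede the stimulus;
    the remaining frames carry the evoked response.
    """

    data: np.ndarray
    frame_period: float  # s
    baseline_frames: int
    pixel_size: float  # um / px
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)
    excluded_trials: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be trials x frames x H x W")
        if not 1 <= self.baseline_frames < self.data.shape[1]:
            raise ValueError("need 1 <= baseline_frames < frames per trial")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name, m in self.roi_masks.items():
            if m.shape != self.data.shape[2:]:
                raise ValueError(f"roi mask {name!r} shape mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def included_trials(self) -> list[int]:
        return [t for t in range((self.n_trials)) if t not in self.excluded_trials]

    @property
    def n_trials_used(self) -> int:
        return self.n_trials - len(self.excluded_trials)


@dataclass
class SpotTemplate:
    """Zero-mean, unit-norm patch averaged from seed transmission spots."""

    patch: np.ndarray
    source_count: int

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        if self.patch.shape[0] % 2 == 0 or self.patch.shape[1] % 2 == 0:
            raise ValueError("template side lengths must be odd")

    @property
    def radius(self) -> int:
        return self.patch.shape[0] // 2


@dataclass
class ReleaseSiteTable:
    """Per-site release events and probabilities.

    ``events`` is a trials x sites boolean array; Pr is defined as the number
    of trials with at least one event at the site divided by the number of
    analysed trials.
    """

    sites: list[tuple[int, float, float]]  # (site_id, x, y)
    events: np.ndarray  # n_trials_used x n_sites bool
    n_trials_used: int
    unassigned_centers: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=bool)
        if self.events.shape[1] != len(self.sites):
            raise ValueError("events column count must equal number of sites")

    @property
    def pr(self) -> np.ndarray:
        return self.events.sum(axis=0) / self.n_trials_used

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "site_id": [s[0] for s in self.sites],
                "x_px": [s[1] for s in self.sites],
                "y_px": [s[2] for s in self.sites],
                "n_events": self.events.sum(axis=0),
                "n_trials": self.n_trials_used,
                "pr": self.pr,
            }
        )


@dataclass
class PrMap:
    """Spot-center occurrence counts accumulated on the pixel grid."""

    grid: np.ndarray  # H x W int counts
    n_trials_used: int

    @property
    def total_centers(self) -> int:
        return int(self.grid.sum())


@dataclass
class QuantalDensityResult:
    """Evoked transmission events per stimulus per um^2 of imaged area."""

    density: float  # events / stimulus / um^2
    total_events: int
    n_trials_used: int
    roi_area: float  # um^2


# ---------------------------------------------------------------------------


def preprocess_stack(
    stack: EpisodeStack, smooth_sigma: float = 0.0, bleach_correct: bool = False
) -> EpisodeStack:
    """Spatially smooth each frame and optionally divide out a bleaching trend.

    The bleaching trend is a straight line fitted to the trial-mean baseline
    intensity as a function of trial index; every trial is divided by its
    fitted relative trend so corrected baselines share a common level.
    """
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be >= 0")
    data = stack.data
    if smooth_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=(0, 0, smooth_sigma, smooth_sigma))
    if bleach_correct:
        if stack.n_trials < 2:
            raise ValueError("bleach correction needs >= 2 trials to fit a trend")
        baseline_means = data[:, : stack.baseline_frames].mean(axis=(1, 2, 3))
        idx = np.arange(stack.n_trials)
        slope, intercept = np.polyfit(idx, baseline_means, 1)
        trend = slope * idx + intercept
        rel = trend / trend.mean()
        if np.any(rel <= 0):
            raise ValueError("fitted bleaching trend crosses zero")
        data = data / rel[:, None, None, None]
    return replace(stack, data=data)


def _focus_metric(frame: np.ndarray) -> float:
    # variance of the Laplacian: drops when the image defocuses
    return float(ndimage.laplace(frame).var())


def qc_trials(
    stack: EpisodeStack,
    motion_limit: float = 2.0,
    focus_drop_limit: float = 0.5,
    response_floor: float | None = None,
    roi_mask: np.ndarray | None = None,
) -> dict[int, list[str]]:
    """Flag trials to exclude: moved, defocused, or failed stimulus.

    Returns a mapping of excluded trial index -> list of reasons.  Motion is
    the registration shift of the trial's baseline image against the median
    baseline image; focus is the high-frequency (Laplacian-variance) metric
    relative to the across-trial median; a stimulus failure is a whole-ROI
    dF maximum below ``response_floor`` (only checked when a floor is given).
    """
    if motion_limit < 0 or focus_drop_limit < 0:
        raise ValueError("limits must be >= 0")
    baselines = stack.data[:, : stack.baseline_frames].mean(axis=1)
    reference = np.median(baselines, axis=0)
    focus = np.array([_focus_metric(b) for b in baselines])
    focus_ref = np.median(focus)

    reasons: dict[int, list[str]] = {}
    for t in range(stack.n_trials):
        why = []
        shift, _, _ = phase_cross_correlation(
            reference, baselines[t], upsample_factor=10, normalization=None
        )
        if np.hypot(*shift) > motion_limit:
            why.append("motion")
        if focus_ref > 0 and (focus_ref - focus[t]) / focus_ref > focus_drop_limit:
            why.append("focus")
        if response_floor is not None:
            dff = compute_delta_f(stack, t)
            region = dff[roi_mask] if roi_mask is not None else dff
            if region.max() < response_floor:
                why.append("stimulus_failure")
        if why:
            reasons[t] = why
    if len(reasons) == stack.n_trials:
        raise ValueError("all trials excluded by QC; nothing to analyze")
    return reasons


def compute_delta_f(stack: EpisodeStack, trial: int) -> np.ndarray:
    """dF image of one trial: mean post-stimulus frames minus mean baseline."""
    if not 0 <= trial < stack.n_trials:
        raise IndexError(f"trial {trial} out of range")
    if trial in stack.excluded_trials:
        raise ValueError(f"trial {trial} is excluded")
    baseline = stack.data[trial, : stack.baseline_frames].mean(axis=0)
    response = stack.data[trial, stack.baseline_frames :].mean(axis=0)
    return response - baseline


def build_template(
    delta_f_images: list[np.ndarray],
    seed_spots: list[tuple[int, float, float]],
    patch_radius: int = 4,
) -> SpotTemplate:
    """Average patches around manually identified spots into a matched template.

    Each seed is (image index, x, y).  Patches are extracted at the rounded
    center, averaged, zero-meaned and normalised to unit Euclidean norm.
    Seeds too close to the border are skipped with a warning.
    """
    if not seed_spots:
        raise ValueError("need at least one seed spot")
    patches = []
    for img_idx, x, y in seed_spots:
        img = delta_f_images[img_idx]
        r, c = int(round(y)), int(round(x))
        if (
            r - patch_radius < 0
            or c - patch_radius < 0
            or r + patch_radius >= img.shape[0]
            or c + patch_radius >= img.shape[1]
        ):
            warnings.warn(
                f"seed spot ({x}, {y}) within patch_radius of border; skipped",
                stacklevel=2,
            )
            continue
        patches.append(
            img[r - patch_radius : r + patch_radius + 1, c - patch_radius : c + patch_radius + 1]
        )
    if not patches:
        raise ValueError("all seed spots skipped (too close to border)")
    patch = np.mean(patches, axis=0)
    patch = patch - patch.mean()
    norm = np.linalg.norm(patch)
    if norm == 0:
        raise ValueError("degenerate (constant) template")
    return SpotTemplate(patch=patch / norm, source_count=len(patches))


def detect_spots(
    delta_f: np.ndarray,
    template: SpotTemplate,
    corr_threshold: float = 0.5,
    min_pixels: int = 4,
    use_local_maxima: bool = False,
) -> list[tuple[float, float]]:
    """Detect transmission-spot centers in one dF image by template matching.

    Pixels whose normalised cross-correlation with the template reaches
    ``corr_threshold`` form participating-pixel regions (8-connectivity);
    regions of at least ``min_pixels`` pixels each yield one center, the
    dF-intensity-weighted centroid of the region (or the region's correlation
    local maximum when ``use_local_maxima``).  Returns (x, y) pixel coords.
    """
    if template.patch.shape[0] > delta_f.shape[0] or template.patch.shape[1] > delta_f.shape[1]:
        raise ValueError("template larger than image")
    corr = match_template(delta_f, template.patch, pad_input=True)
    # zero-padding makes the correlation unreliable within a template radius
    # of the border; exclude that margin
    r = template.radius
    corr[:r, :] = corr[-r:, :] = 0.0
    corr[:, :r] = corr[:, -r:] = 0.0
    mask = corr >= corr_threshold
    labels = cc_label(mask, connectivity=2)
    centers: list[tuple[float, float]] = []
    for region in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == region)
        if rr.size < min_pixels:
            continue
        if use_local_maxima:
            k = np.argmax(corr[rr, cc])
            centers.append((float(cc[k]), float(rr[k])))
        else:
            w = np.clip(delta_f[rr, cc], 0, None)
            if w.sum() == 0:
                w = np.ones_like(w)
            centers.append((float(np.average(cc, weights=w)), float(np.average(rr, weights=w))))
    return centers


def detect_spots_by_trial(
    stack: EpisodeStack,
    template: SpotTemplate,
    corr_threshold: float = 0.5,
    min_pixels: int = 4,
) -> dict[int, list[tuple[float, float]]]:
    """Run spot detection on every included trial's dF image."""
    return {
        t: detect_spots(compute_delta_f(stack, t), template, corr_threshold, min_pixels)
        for t in stack.included_trials
    }


def build_pr_map(
    centers_by_trial: dict[int, list[tuple[float, float]]],
    shape: tuple[int, int],
    n_trials_used: int,
) -> PrMap:
    """Accumulate spot-center occurrences per pixel across trials."""
    grid = np.zeros(shape, dtype=int)
    for centers in centers_by_trial.values():
        for x, y in centers:
            r, c = int(round(y)), int(round(x))
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"center ({x}, {y}) outside map of shape {shape}")
            grid[r, c] += 1
    return PrMap(grid=grid, n_trials_used=n_trials_used)


def assign_sites_and_pr(
    centers_by_trial: dict[int, list[tuple[float, float]]],
    site_locations: list[tuple[float, float]],
    capture_radius: float,
    n_trials_used: int | None = None,
) -> ReleaseSiteTable:
    """Assign detected centers to release sites and compute per-site Pr.

    Each center goes to the nearest site within ``capture_radius``; a site
    scores one event per trial regardless of how many centers land on it.
    Centers matching no site are reported in ``unassigned_centers`` (they
    still count toward quantal density, which is site-agnostic).
    """
    if capture_radius <= 0:
        raise ValueError("capture_radius must be positive")
    if not site_locations:
        raise ValueError("site_locations must be non-empty")
    sites = np.asarray(site_locations, dtype=float)
    if len(sites) >= 2:
        from scipy.spatial.distance import pdist

        if pdist(sites).min() < capture_radius:
            raise ValueError(
                "two sites closer than capture_radius: assignment ambiguous"
            )
    if n_trials_used is None:
        n_trials_used = len(centers_by_trial)
    trial_ids = sorted(centers_by_trial)
    events = np.zeros((len(trial_ids), len(sites)), dtype=bool)
    unassigned: list[tuple[int, float, float]] = []
    for row, t in enumerate(trial_ids):
        for x, y in centers_by_trial[t]:
            d = np.hypot(sites[:, 0] - x, sites[:, 1] - y)
            k = int(np.argmin(d))
            if d[k] <= capture_radius:
                events[row, k] = True
            else:
                unassigned.append((t, x, y))
    return ReleaseSiteTable(
        sites=[(i, float(x), float(y)) for i, (x, y) in enumerate(sites)],
        events=events,
        n_trials_used=n_trials_used,
        unassigned_centers=unassigned,
    )


def quantal_density(
    centers_by_trial: dict[int, list[tuple[float, float]]],
    n_trials_used: int,
    roi_mask: np.ndarray,
    pixel_size: float,
) -> QuantalDensityResult:
    """Quantal density: spot centers inside the ROI per trial per um^2."""
    if n_trials_used < 1:
        raise ValueError("n_trials_used must be >= 1")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n_px = int(roi_mask.sum())
    if n_px == 0:
        raise ValueError("zero-area ROI mask")
    area = n_px * pixel_size**2
    total = 0
    for centers in centers_by_trial.values():
        for x, y in centers:
            r, c = int(round(y)), int(round(x))
            if 0 <= r < roi_mask.shape[0] and 0 <= c < roi_mask.shape[1] and roi_mask[r, c]:
                total += 1
    return QuantalDensityResult(
        density=total / (n_trials_used * area),
        total_events=total,
        n_trials_used=n_trials_used,
        roi_area=area,
    )
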