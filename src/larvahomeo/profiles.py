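"""Gaussian line-profile analysis for super-resolution synapse images.

Intensity line profiles (~1 um long) drawn across individual synaptic puncta
are fitted per channel with a Gaussian plus offset.  Profiles are then
re-centered on the sample nearest each fitted peak (true peak samples are
sensitive to local maxima), averaged on a fixed grid of 42.5 nm steps within
+/-0.4 um of the center, and a second Gaussian fit to the mean curve yields
the final full width at half maximum, FWHM = 2.355 * sigma
(2 * sqrt(2 ln 2) = 2.3548..., quoted at the conventional 3-significant-digit
value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FWHM_FACTOR",
    "LineProfile",
    "GaussianFitResult",
    "AveragedProfile",
    "gaussian_model",
    "fit_gaussian",
    "center_profiles",
    "fit_averaged",
]

#: conventional Gaussian FWHM / sigma ratio (2 * sqrt(2 ln 2) to 4 s.f. is 2.3548)
FWHM_FACTOR = 2.355


@dataclass
class LineProfile:
    """Sampled intensity along a line, one column per channel."""

    position: np.ndarray  # um
    intensity: np.ndarray  # n_samples or n_samples x n_channels
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.position) < 8:
            raise ValueError("need >= 8 samples")
        if self.intensity.ndim == 1:
            self.intensity = self.intensity[:, None]
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.intensity.shape[1])]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]


@dataclass
class GaussianFitResult:
    """offset + amplitude * exp(-(x - center)^2 / (2 sigma^2)) least-squares fit."""

    amplitude: float
    center: float  # um
    sigma: float  # um
    offset: float
    rss: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.rss < 0:
            raise ValueError("rss must be non-negative")

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma


@dataclass
class AveragedProfile:
    """Peak-centered mean +/- SEM intensity on the fixed averaging grid."""

    grid: np.ndarray  # um, symmetric about 0
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # profiles contributing per grid point


def gaussian_model(x, amplitude, center, sigma, offset):
    return offset + amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def _moment_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    offset = float(y.min())
    amplitude = float(y.max() - y.min())
    w = np.clip(y - offset, 0, None)
    if w.sum() == 0:
        raise ValueError("constant profile: nothing to fit")
    center = float(np.average(x, weights=w))
    sigma = float(np.sqrt(np.average((x - center) ** 2, weights=w)))
    return amplitude, center, max(sigma, np.diff(x).min()), offset


def fit_gaussian(profile: LineProfile, channel: int | str = 0) -> GaussianFitResult:
    """Least-squares Gaussian fit of one channel of a line profile.

    Initial values come from intensity moments (offset = min, amplitude =
    max - min, center and sigma = intensity-weighted mean and SD).  A fit
    whose sigma exceeds the sampled span, or that fails to converge, is
    rejected.
    """
    if isinstance(channel, str):
        channel = profile.channel_labels.index(channel)
    x = profile.position
    y = profile.intensity[:, channel]
    if np.ptp(y) == 0:
        raise ValueError("constant-intensity profile cannot be fitted")
    p0 = _moment_init(x, y)
    span = float(x[-1] - x[0])
    try:
        popt, _ = curve_fit(gaussian_model, x, y, p0=p0, maxfev=5000)
    except RuntimeError as exc:
        raise ValueError(f"Gaussian fit did not converge: {exc}") from exc
    amplitude, center, sigma, offset = popt
    sigma = abs(float(sigma))
    if sigma > span:
        raise ValueError(f"fitted sigma {sigma:.3g} um exceeds profile span {span:.3g} um")
    rss = float(np.sum((gaussian_model(x, amplitude, center, sigma, offset) - y) ** 2))
    return GaussianFitResult(
        amplitude=float(amplitude), center=float(center), sigma=sigma,
        offset=float(offset), rss=rss,
    )


def make_grid(half_window: float = 0.4, step: float = 0.0425) -> np.ndarray:
    """Symmetric averaging grid: multiples of ``step`` within +/-``half_window``."""
    k = int(np.floor(half_window / step + 1e-9))
    return step * np.arange(-k, k + 1)


def center_profiles(
    profiles: list[LineProfile],
    fits: list[GaussianFitResult],
    channel: int | str = 0,
    half_window: float = 0.4,
    step: float = 0.0425,
) -> AveragedProfile:
    """Average profiles after re-centering each on its fitted peak.

    Each profile is shifted so the sample nearest its fitted center sits at 0,
    then samples are binned to the nearest grid point (42.5 nm spacing within
    +/-0.4 um by default).  Mean and SEM are computed per grid point; a single
    contributing profile reports SEM 0 with n = 1.  Profiles whose fitted
    center falls outside their sampled span are excluded with a warning.
    """
    grid = make_grid(half_window, step)
    sums = np.zeros((len(grid),))
    sq_sums = np.zeros((len(grid),))
    counts = np.zeros(len(grid), dtype=int)
    for prof, fit in zip(profiles, fits):
        ch = prof.channel_labels.index(channel) if isinstance(channel, str) else channel
        x, y = prof.position, prof.intensity[:, ch]
        if not (x[0] <= fit.center <= x[-1]):
            warnings.warn(
                f"fitted center {fit.center:.3g} um outside sampled span; profile excluded",
                stacklevel=2,
            )
            continue
        anchor = x[np.argmin(np.abs(x - fit.center))]
        shifted = x - anchor
        for xs, ys in zip(shifted, y):
            if abs(xs) > half_window + step / 2:
                continue
            k = int(np.argmin(np.abs(grid - xs)))
            sums[k] += ys
            sq_sums[k] += ys**2
            counts[k] += 1
    if not counts.any():
        raise ValueError("no profiles contributed to the averaging grid")
    keep = counts > 0
    mean = np.full(len(grid), np.nan)
    sem = np.zeros(len(grid))
    mean[keep] = sums[keep] / counts[keep]
    multi = counts > 1
    var = np.zeros(len(grid))
    var[multi] = (sq_sums[multi] - counts[multi] * mean[multi] ** 2) / (counts[multi] - 1)
    sem[multi] = np.sqrt(np.clip(var[multi], 0, None) / counts[multi])
    return AveragedProfile(grid=grid[keep], mean=mean[keep], sem=sem[keep], n=counts[keep])


def fit_averaged(avg: AveragedProfile) -> GaussianFitResult:
    """Gaussian fit of the averaged mean curve; its FWHM is the final readout."""
    if len(avg.grid) < 8:
        raise ValueError("need >= 8 grid points with data")
    prof = LineProfile(position=avg.grid, intensity=avg.mean)
    return fit_gaussian(prof, 0)
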