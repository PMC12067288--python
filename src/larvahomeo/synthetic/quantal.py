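"""Synthetic episodic quantal-imaging stacks with ground-truth release events.

Emulates nerve-stimulation trials at the larval NMJ imaged with a postsynaptic
calcium indicator: each trial is a short frame sequence with a few baseline
frames, after which each synaptic site releases (or fails) as an independent
Bernoulli draw.  A release adds a point-spread-function-shaped fluorescence
transient at the site; i.i.d. Gaussian read noise is added everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..quantal import EpisodeStack, ReleaseSiteTable

__all__ = ["QuantalSimConfig", "gen_quantal_episodes"]


@dataclass
class QuantalSimConfig:
    """Parameters of the episodic quantal-release simulation.

    The default protocol mirrors a standard optical quantal-analysis
    acquisition: 10 frames per stimulus episode with 3 baseline frames
    before the stimulus.
    """

    site_positions: list[tuple[float, float]]  # (x, y) pixel coords
    site_pr: list[float]  # per-site release probability per trial
    n_trials: int = 100
    frames_per_trial: int = 10
    baseline_frames: int = 3
    psf_sigma: float = 1.5  # px
    event_amplitude: float = 50.0  # dF intensity units
    noise_sd: float = 10.0  # intensity units
    pixel_size: float = 0.2  # um/px
    image_shape: tuple[int, int] = (48, 48)
    baseline_level: float = 100.0  # resting fluorescence, intensity units
    resting_amplitude: float = 20.0  # resting NMJ fluorescence above background
    texture_sd: float = 5.0  # static background texture, intensity units
    decay_per_frame: float = 0.65  # indicator decay factor per post-onset frame
    bleach_per_trial: float = 0.0  # fractional multiplicative decay across trials
    frame_period: float = 0.05  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.site_positions) != len(self.site_pr):
            raise ValueError("site_positions and site_pr must have equal length")
        for p in self.site_pr:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"site_pr must be in [0, 1], got {p}")
        if not 1 <= self.baseline_frames < self.frames_per_trial:
            raise ValueError("need 1 <= baseline_frames < frames_per_trial")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        H, W = self.image_shape
        for x, y in self.site_positions:
            if not (0 <= x < W and 0 <= y < H):
                raise ValueError(f"site ({x}, {y}) outside image {self.image_shape}")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


def _gaussian_blob(shape: tuple[int, int], x0: float, y0: float, sigma: float) -> np.ndarray:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    return np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))


def gen_quantal_episodes(
    cfg: QuantalSimConfig,
) -> tuple[EpisodeStack, ReleaseSiteTable]:
    """Simulate an episodic stimulation stack plus its ground truth.

    Returns
    -------
    stack : EpisodeStack
        trials x frames x H x W intensity data.
    truth : ReleaseSiteTable
        Per-(trial, site) release indicators and the true empirical Pr
        (events / trials) realised by the Bernoulli draws.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = np.asarray(cfg.site_positions, dtype=float)

    # flag detection-ambiguous geometry
    if len(positions) >= 2:
        from scipy.spatial.distance import pdist

        if pdist(positions).min() < cfg.psf_sigma:
            warnings.warn(
                "synaptic sites closer than one psf_sigma: spot detection may be "
                "ambiguous",
                stacklevel=2,
            )

    H, W = cfg.image_shape
    events = rng.random((cfg.n_trials, cfg.n_sites)) < np.asarray(cfg.site_pr)

    # single-frame rise at the first post-baseline frame, then geometric decay
    n_post = cfg.frames_per_trial - cfg.baseline_frames
    time_course = cfg.decay_per_frame ** np.arange(n_post)

    blobs = np.stack(
        [_gaussian_blob((H, W), x, y, cfg.psf_sigma) for x, y in positions]
    )  # sites x H x W

    # resting NMJ fluorescence gives every frame spatial structure, as with a
    # real postsynaptic indicator at rest (also what registration QC keys on);
    # per-site brightness varies so the scene has no translational symmetry
    resting_weights = rng.uniform(0.5, 1.5, cfg.n_sites)
    resting = cfg.baseline_level + cfg.resting_amplitude * np.tensordot(
        resting_weights, blobs, axes=1
    )
    if cfg.texture_sd > 0:
        # static muscle-autofluorescence texture, constant across frames
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.normal(0.0, 1.0, (H, W)), 3.0)
        resting = resting + cfg.texture_sd * tex / tex.std()
    data = np.broadcast_to(
        resting, (cfg.n_trials, cfg.frames_per_trial, H, W)
    ).copy()
    for t in range(cfg.n_trials):
        if cfg.bleach_per_trial:
            data[t] *= (1.0 - cfg.bleach_per_trial) ** t
        active = np.flatnonzero(events[t])
        if active.size:
            signal = cfg.event_amplitude * blobs[active].sum(axis=0)
            data[t, cfg.baseline_frames :] += time_course[:, None, None] * signal[None]
    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)

    stack = EpisodeStack(
        data=data,
        frame_period=cfg.frame_period,
        baseline_frames=cfg.baseline_frames,
        pixel_size=cfg.pixel_size,
    )
    truth = ReleaseSiteTable(
        sites=[(i, float(x), float(y)) for i, (x, y) in enumerate(positions)],
        events=events,
        n_trials_used=cfg.n_trials,
    )
    return stack, truth
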