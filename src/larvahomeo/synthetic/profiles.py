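"""Synthetic noisy Gaussian line profiles with known truth parameters."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..profiles import LineProfile, gaussian_model

__all__ = ["ProfileSimConfig", "gen_line_profiles"]


@dataclass
class ProfileSimConfig:
    """Parameters of the line-profile simulation.

    The sample grid matches the averaging protocol: 42.5 nm steps within
    +/-0.4 um of the nominal center.  ``center_jitter_sd`` shifts each
    profile's true center to emulate imperfect line placement.
    """

    sigma: float = 0.12  # um
    center: float = 0.0  # um
    amplitude: float = 1000.0  # intensity
    offset: float = 100.0  # intensity
    sample_step: float = 0.0425  # um
    half_window: float = 0.4  # um
    n_profiles: int = 50
    noise_sd: float = 50.0  # intensity
    center_jitter_sd: float = 0.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.sample_step <= 0:
            raise ValueError("sample_step must be positive")
        if self.half_window < self.sample_step:
            raise ValueError("half_window must be >= sample_step")


def gen_line_profiles(
    cfg: ProfileSimConfig,
) -> tuple[list[LineProfile], list[dict[str, float]]]:
    """Simulate profiles sampling offset + A exp(-(x-c)^2 / 2 sigma^2) + noise.

    Returns the profiles and a truth dict (amplitude, center, sigma, offset)
    per profile.
    """
    rng = np.random.default_rng(cfg.seed)
    k = int(np.floor(cfg.half_window / cfg.sample_step + 1e-9))
    x = cfg.center + cfg.sample_step * np.arange(-k, k + 1)
    profiles, truths = [], []
    for _ in range(cfg.n_profiles):
        c = cfg.center + (
            rng.normal(0, cfg.center_jitter_sd) if cfg.center_jitter_sd > 0 else 0.0
        )
        y = gaussian_model(x, cfg.amplitude, c, cfg.sigma, cfg.offset)
        if cfg.noise_sd > 0:
            y = y + rng.normal(0, cfg.noise_sd, size=x.shape)
        profiles.append(LineProfile(position=x.copy(), intensity=y))
        truths.append(
            {
                "amplitude": cfg.amplitude,
                "center": c,
                "sigma": cfg.sigma,
                "offset": cfg.offset,
            }
        )
    return profiles, truths
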