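"""Synthetic larval crawl sessions with ground-truth phase labels.

The trajectory alternates among scheduled phases: *crawl* (straight-line
peristaltic advance with stride-periodic speed modulation and low body
curvature), *reorient* (centroid held in place, high curvature from head
sweeping, heading changes at the end), and *stop* (held in place, low
curvature).  Each frame also carries a midline — a circular arc of the
frame's true curvature, scaled to the body length — so the midline-fitting
pipeline can be validated against known curvature truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..behavior import LarvaTrack

__all__ = ["CrawlSimConfig", "CrawlTruth", "gen_crawl_session"]


@dataclass
class CrawlSimConfig:
    """Parameters of the crawl/reorient/stop trajectory simulation."""

    phase_schedule: list[tuple[str, float]]  # (label, duration s)
    crawl_speed: float = 0.8  # mm/s
    stride_period: float = 1.0  # s
    reorient_curvature_scale: float = 1.0  # mm^-1
    crawl_curvature_scale: float = 0.05  # mm^-1, well below the reorient scale
    body_length: float = 3.5  # mm
    frame_rate: float = 10.0  # Hz
    heading_change_per_reorient: float = 60.0  # degrees
    noise_sd_position: float = 0.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.phase_schedule:
            raise ValueError("phase_schedule must be non-empty")
        for label, dur in self.phase_schedule:
            if label not in ("crawl", "reorient", "stop"):
                raise ValueError(f"unknown phase label {label!r}")
            if dur <= 0:
                raise ValueError("phase durations must be positive")
        if self.frame_rate <= 0 or self.body_length <= 0:
            raise ValueError("frame_rate and body_length must be positive")


@dataclass
class CrawlTruth:
    """Per-frame ground truth for a simulated session."""

    labels: np.ndarray  # phase label per frame
    kappa: np.ndarray  # true body curvature per frame, mm^-1
    heading: np.ndarray  # degrees per frame
    heading_changes: list[float]  # signed change at each reorientation, degrees


def _arc_midline(center: np.ndarray, heading_deg: float, kappa: float,
                 body_length: float, n_points: int = 11) -> np.ndarray:
    """Midline as a circular arc of curvature kappa, arc length body_length."""
    s = np.linspace(-body_length / 2, body_length / 2, n_points)
    if kappa < 1e-9:
        local = np.stack([s, np.zeros_like(s)], axis=1)
    else:
        r = 1.0 / kappa
        theta = s / r
        local = np.stack([r * np.sin(theta), r * (1 - np.cos(theta))], axis=1)
    a = np.radians(heading_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return center + local @ rot.T


def gen_crawl_session(cfg: CrawlSimConfig) -> tuple[LarvaTrack, CrawlTruth]:
    """Simulate a crawl session; returns the track (with midlines) and truth.

    Crawl phases advance along the current heading with arc length
    s(t) = v * (t - (T/2pi) sin(2pi t / T)): the instantaneous speed
    v (1 - cos(2pi t/T)) pulses with the stride period T and averages to v,
    so a phase covering whole stride periods displaces exactly v * duration.
    Reorient phases hold position, draw curvature near the reorient scale,
    and rotate the heading by +/-heading_change_per_reorient on exit.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.frame_rate

    ts, xs, labels, kappas, headings = [], [], [], [], []
    heading = 0.0
    pos = np.zeros(2)
    t_global = 0.0
    heading_changes: list[float] = []

    for label, duration in cfg.phase_schedule:
        n = int(round(duration * cfg.frame_rate))
        tau = np.arange(1, n + 1) * dt  # time within phase at each frame end
        T = cfg.stride_period
        # smooth stride-locked body wiggle: brief curvature peaks each stride,
        # so crawl-phase exceedances of any within-distribution threshold are
        # far shorter than the reorientation minimum duration
        wiggle = np.abs(np.sin(2 * np.pi * tau / T)) * (0.9 + 0.2 * rng.random(n))
        if label == "crawl":
            arc = cfg.crawl_speed * (tau - (T / (2 * np.pi)) * np.sin(2 * np.pi * tau / T))
            direction = np.array([np.cos(np.radians(heading)), np.sin(np.radians(heading))])
            frame_pos = pos + arc[:, None] * direction
            frame_kappa = cfg.crawl_curvature_scale * wiggle
            pos = frame_pos[-1].copy()
        else:
            frame_pos = np.tile(pos, (n, 1))
            if label == "reorient":
                # head sweep: curvature well above the crawl scale throughout
                frame_kappa = cfg.reorient_curvature_scale * (0.8 + 0.4 * rng.random(n))
            else:  # stop
                frame_kappa = 0.5 * cfg.crawl_curvature_scale * wiggle
        for k in range(n):
            ts.append(t_global)
            xs.append(frame_pos[k])
            labels.append(label)
            kappas.append(frame_kappa[k])
            headings.append(heading)
            t_global += dt
        if label == "reorient":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            change = sign * cfg.heading_change_per_reorient
            heading_changes.append(change)
            heading += change

    t = np.asarray(ts)
    xy = np.asarray(xs)
    if cfg.noise_sd_position > 0:
        xy = xy + rng.normal(0, cfg.noise_sd_position, size=xy.shape)
    kappa = np.asarray(kappas)
    midlines = [
        _arc_midline(xy[i], headings[i], kappa[i], cfg.body_length) for i in range(len(t))
    ]
    track = LarvaTrack(t=t, centroid=xy, frame_rate=cfg.frame_rate, midline=midlines)
    truth = CrawlTruth(
        labels=np.asarray(labels, dtype=object),
        kappa=kappa,
        heading=np.asarray(headings),
        heading_changes=heading_changes,
    )
    return track, truth
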