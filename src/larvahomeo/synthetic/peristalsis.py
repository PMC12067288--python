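"""Synthetic multi-segment dF/F bout trains with peristaltic-wave structure.

Waves arrive as a refractory Poisson process; each wave triggers one bout per
abdominal segment with onsets staggered by the intersegmental delay in the
wave's direction (posterior-to-anterior with probability
``wave_direction_prob_PA``).  A bout is a trapezoid: linear rise to the bout
amplitude, plateau, linear fall, with total duration
``bout_duration * duration_scale`` — the ``duration_scale`` knob emulates the
prolonged-bout phenotype of synaptically weakened animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..bouts import FluorTrace

__all__ = ["PeristalsisSimConfig", "TruthBout", "TruthWave", "gen_peristaltic_traces"]


@dataclass
class PeristalsisSimConfig:
    """Parameters of the peristaltic bout-train simulation.

    Segments are labelled A2..A(n+1) anterior-to-posterior.  Defaults emulate
    a 10 min recording at 20 Hz with ~2 waves/min.
    """

    n_segments: int = 3
    wave_rate: float = 2.0  # waves / min
    bout_duration: float = 2.0  # s
    intersegmental_delay: float = 0.3  # s
    bout_amplitude: float = 1.0  # dF/F
    rise_time: float = 0.4  # s
    noise_sd: float = 0.02  # dF/F
    duration_scale: float = 1.0  # "weakened" condition multiplier
    record_length: float = 600.0  # s
    frame_rate: float = 20.0  # Hz
    wave_direction_prob_PA: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bout_duration <= 0:
            raise ValueError("bout_duration must be positive")
        if not 0.0 <= self.wave_direction_prob_PA <= 1.0:
            raise ValueError("wave_direction_prob_PA must be in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_segments < 2:
            raise ValueError("need >= 2 segments")

    @property
    def segment_labels(self) -> list[str]:
        return [f"A{i + 2}" for i in range(self.n_segments)]  # anterior -> posterior

    @property
    def total_duration(self) -> float:
        return self.bout_duration * self.duration_scale


@dataclass
class TruthBout:
    segment: str
    onset: float
    offset: float
    wave_id: int
    merged: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class TruthWave:
    wave_id: int
    direction: str  # "P->A" or "A->P"
    t0: float  # onset of the leading segment's bout
    member_segments: list[str]


def _bout_shape(tau: np.ndarray, amplitude: float, rise: float, total: float) -> np.ndarray:
    """Trapezoidal dF/F time course: rise, plateau, symmetric fall."""
    rise = min(rise, total / 2)
    fall_start = total - rise
    y = np.zeros_like(tau)
    m = (tau >= 0) & (tau < rise)
    y[m] = amplitude * tau[m] / rise
    m = (tau >= rise) & (tau < fall_start)
    y[m] = amplitude
    m = (tau >= fall_start) & (tau < total)
    y[m] = amplitude * (total - tau[m]) / rise
    return y


def gen_peristaltic_traces(
    cfg: PeristalsisSimConfig,
) -> tuple[dict[str, FluorTrace], list[TruthBout], list[TruthWave]]:
    """Simulate per-segment dF/F traces plus truth bout and wave tables.

    Wave inter-arrival = refractory period (one full bout duration plus the
    total intersegmental span) + exponential waiting time chosen so the mean
    interval matches ``wave_rate``; this keeps bouts of successive waves from
    merging, so truth stays unambiguous.  Should bouts overlap anyway they
    are flagged ``merged`` in the truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.segment_labels
    span = cfg.intersegmental_delay * (cfg.n_segments - 1)
    refractory = cfg.total_duration + span
    mean_interval = 60.0 / cfg.wave_rate
    exp_mean = mean_interval - refractory
    if exp_mean <= 0:
        raise ValueError(
            "wave_rate too high for the bout duration: refractory period "
            f"{refractory:.2f}s exceeds mean interval {mean_interval:.2f}s"
        )

    # wave onset times (time of the leading segment's bout onset)
    onsets = []
    t = float(refractory + rng.exponential(exp_mean))
    while t + refractory < cfg.record_length:
        onsets.append(t)
        t += refractory + rng.exponential(exp_mean)

    truth_bouts: list[TruthBout] = []
    truth_waves: list[TruthWave] = []
    n_frames = int(round(cfg.record_length * cfg.frame_rate))
    time = np.arange(n_frames) / cfg.frame_rate
    dff = {seg: np.zeros(n_frames) for seg in labels}

    for wid, t0 in enumerate(onsets):
        pa = rng.random() < cfg.wave_direction_prob_PA
        direction = "P->A" if pa else "A->P"
        seg_seq = labels[::-1] if pa else labels  # leading segment first
        truth_waves.append(
            TruthWave(wave_id=wid, direction=direction, t0=t0, member_segments=list(seg_seq))
        )
        for k, seg in enumerate(seg_seq):
            onset = t0 + k * cfg.intersegmental_delay
            offset = onset + cfg.total_duration
            dff[seg] += _bout_shape(
                time - onset, cfg.bout_amplitude, cfg.rise_time, cfg.total_duration
            )
            truth_bouts.append(TruthBout(segment=seg, onset=onset, offset=offset, wave_id=wid))

    # flag merged bouts (same segment, overlapping in time)
    by_seg: dict[str, list[TruthBout]] = {seg: [] for seg in labels}
    for b in truth_bouts:
        by_seg[b.segment].append(b)
    for seg_bouts in by_seg.values():
        seg_bouts.sort(key=lambda b: b.onset)
        for a, b in zip(seg_bouts, seg_bouts[1:]):
            if b.onset < a.offset:
                a.merged = b.merged = True

    traces = {}
    for seg in labels:
        y = dff[seg]
        if cfg.noise_sd > 0:
            y = y + rng.normal(0, cfg.noise_sd, size=n_frames)
        traces[seg] = FluorTrace(t=time, dff=y, roi_id=seg)
    return traces, truth_bouts, truth_waves
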