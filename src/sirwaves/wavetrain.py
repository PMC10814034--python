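"""Wavetrains: sequences of news waves spliced on the active spreaders.

A new piece of news, similar to but distinct from the previous one, is
launched at a splice time t_k while the previous wave still has I(t_k)
active spreaders.  Those spreaders seed the next wave: the new segment
starts with I(0) = I_prev(t_k), R(0) = 0 and S(0) = N - I(0) — the news is
new, so nobody has yet lost interest in it and the susceptible pool resets.
I is therefore continuous across splices by construction, while S and R
jump.

Splicing while I(t_k) exceeds the segment's own I(0) raises every
subsequent amplitude (an *increasing* wavetrain — the regime interesting
for advertising or propaganda); splicing during deep decay lowers it
(*decreasing*); anything else is *mixed*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .analytic_solutions import RiccatiWaveM2
from .core_model import SIRParams
from .exceptions import DeadSpliceError, InfeasibleSpliceError, ParameterError
from .wave_metrics import WaveMetrics, compute_metrics

__all__ = [
    "WaveSegment",
    "WavetrainSpec",
    "Wavetrain",
    "compose_wavetrain",
    "classify_train",
    "DEFAULT_PEAK_FRACTION",
]

#: Default splice point as a fraction of the running segment's peak time.
#: A fraction in (1, 2) splices after the peak while I(t) is still above the
#: segment's own I(0) (the sech^2 pulse is symmetric about its peak), which
#: is the regime that produces an increasing train of distinct humps.
DEFAULT_PEAK_FRACTION = 1.5


@dataclass(frozen=True)
class WaveSegment:
    """One wave of the train: its rates and how long it runs.

    Exactly one of ``duration`` (absolute, on the segment's own clock) or
    ``peak_fraction`` (duration = fraction x the segment's peak time) must
    be given.
    """

    tau: float
    rho: float
    duration: float | None = None
    peak_fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.duration is None) == (self.peak_fraction is None):
            raise ParameterError("give exactly one of duration or peak_fraction")
        if self.duration is not None and self.duration <= 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        if self.peak_fraction is not None and self.peak_fraction <= 0:
            raise ParameterError(f"peak_fraction must be positive, got {self.peak_fraction}")


@dataclass(frozen=True)
class WavetrainSpec:
    """Population, seed spreaders and the ordered list of segments."""

    N: float
    I0: float
    segments: Sequence[WaveSegment]
    model: str = "analytic-m2-d0"
    n_points_per_segment: int = 1001

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise ParameterError("a wavetrain needs at least one segment")
        if self.model != "analytic-m2-d0":
            raise ParameterError(f"unsupported wavetrain model {self.model!r}")
        if not (0 < self.I0 < self.N):
            raise ParameterError("need 0 < I0 < N")


@dataclass(frozen=True)
class Wavetrain:
    """Composed train: concatenated samples plus per-segment summaries."""

    frame: pd.DataFrame           # columns t, S, I, R, segment (global clock)
    splice_times: tuple           # global times t_1..t_{k-1}
    segment_metrics: tuple        # WaveMetrics per segment, each on its own clock
    segment_amplitudes: tuple     # max I within each segment's actual window
    segment_peak_times_global: tuple
    segments: tuple               # the solved Trajectory of each segment (own clock)
    train_class: str = field(default="")


def _segment_amplitude(wave: RiccatiWaveM2, duration: float) -> tuple[float, float]:
    """(max I on [0, duration], its local time) using the closed-form peak."""
    tm = wave.peak_time
    if 0.0 < tm <= duration:
        return float(wave.peak_amplitude), float(tm)
    if tm <= 0.0:
        return float(wave.I(0.0)), 0.0
    return float(wave.I(duration)), float(duration)  # cut before its peak


def compose_wavetrain(spec: WavetrainSpec) -> Wavetrain:
    """Solve each segment with spliced initial conditions and concatenate."""
    N = spec.N
    I_cur = float(spec.I0)
    offset = 0.0
    floor = 1e-12 * N
    frames, splices, metrics, amps, peaks_global, trajs = [], [], [], [], [], []
    for idx, seg in enumerate(spec.segments):
        if I_cur >= N:
            raise InfeasibleSpliceError(f"segment {idx}: spliced I(0) = {I_cur:g} >= N")
        if I_cur <= floor:
            raise DeadSpliceError(f"segment {idx}: splice after extinction (I = {I_cur:g})")
        params = SIRParams.from_initial_spreaders(N, seg.tau, seg.rho, I0=I_cur)
        wave = RiccatiWaveM2(params=params, D=0.0, E=1.0)
        if seg.duration is not None:
            dur = seg.duration
        else:
            if wave.peak_time <= 0.0:
                raise ParameterError(
                    f"segment {idx}: peak_fraction splice needs a growing wave "
                    f"(Rn(0) = {params.Rn0:g} <= 1)")
            dur = seg.peak_fraction * wave.peak_time
        t_local = np.linspace(0.0, dur, spec.n_points_per_segment)
        traj = wave.trajectory(t_local)
        trajs.append(traj)
        metrics.append(compute_metrics(wave))
        amp, tm_local = _segment_amplitude(wave, dur)
        amps.append(amp)
        peaks_global.append(offset + tm_local)
        frames.append(pd.DataFrame({
            "t": offset + t_local, "S": traj.S, "I": traj.I, "R": traj.R,
            "segment": idx}))
        I_cur = float(wave.I(dur))  # continuity: next segment starts here exactly
        offset += dur
        if idx < len(spec.segments) - 1:
            splices.append(offset)
    frame = pd.concat(frames, ignore_index=True)
    train = Wavetrain(
        frame=frame,
        splice_times=tuple(splices),
        segment_metrics=tuple(metrics),
        segment_amplitudes=tuple(amps),
        segment_peak_times_global=tuple(peaks_global),
        segments=tuple(trajs),
        train_class=classify_train(amps),
    )
    return train


def classify_train(amplitudes: Sequence[float] | Sequence[WaveMetrics]) -> str:
    """increasing | decreasing | mixed by strict amplitude ordering.

    A single segment is 'increasing' by convention (flagged with a warning).
    Ties (amplitudes equal to within 1e-12 relative) are neither strictly
    increasing nor decreasing, hence 'mixed'.
    """
    amps = [a.Im if isinstance(a, WaveMetrics) else float(a) for a in amplitudes]
    if len(amps) < 2:
        warnings.warn("single-segment train classified 'increasing' by convention",
                      RuntimeWarning, stacklevel=2)
        return "increasing"
    scale = max(abs(a) for a in amps) or 1.0
    diffs = np.diff(amps)
    if np.all(diffs > 1e-12 * scale):
        return "increasing"
    if np.all(diffs < -1e-12 * scale):
        return "decreasing"
    return "mixed"
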