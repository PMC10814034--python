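"""Wave characteristics: amplitude, time horizon, Rn = 1 crossing, sweeps, typology.

The amplitude I_m is the maximum number of simultaneously active spreaders;
the time t_m at which it is reached is the *time horizon* of the wave.  At an
interior maximum dI/dt = 0, so sigma(t_m) = 0 and Rn(t_m) = 1: the peak and
the Rn = 1 downcrossing coincide.  Waves that start with Rn(0) <= 1 never
grow; their horizon is reported as 0 with I_m = I(0).

``sensitivity_sweep`` exposes the directional laws of the theory: I_m grows
with I(0), N and tau and shrinks with rho; t_m shrinks with I(0) and tau and
grows with N.  ``classify_wave_type`` places a (tau, rho) pair in the
quadrant typology A-E (high/low transmission x high/low recovery, E the
intermediate band).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .analytic_solutions import RiccatiWaveM2, WaveM3
from .chain_reduction import validity_bound
from .core_model import SIRParams, Trajectory, growth_rate
from .exceptions import ConfigError, HorizonNotReachedError, ParameterError

__all__ = [
    "WaveMetrics",
    "WaveTypeThresholds",
    "DEFAULT_THRESHOLDS",
    "compute_metrics",
    "sensitivity_sweep",
    "classify_wave_type",
]

#: Auto-extension of the time window doubles t_end at most this many times
#: (2**10 overall) before giving up on finding the peak.
MAX_DOUBLINGS = 10


@dataclass(frozen=True)
class WaveMetrics:
    """Summary of one wave.

    ``t_Rn1`` is the time of the Rn = 1 downcrossing (None when the wave
    never grows), ``validity_max`` the largest Taylor validity bound along
    the wave (None when no truncation order applies, e.g. full-SIR runs
    without a comparison order).
    """

    Im: float
    tm: float
    t_Rn1: float | None
    R_final: float
    validity_max: float | None


def _auto_t_end(wave, start: float) -> float:
    """Double the window until I has passed its peak (I(t_end) < max so far)."""
    t_end = start
    for _ in range(MAX_DOUBLINGS + 1):
        t = np.linspace(0.0, t_end, 513)
        I = wave.I(t)
        if int(np.argmax(I)) < I.size - 1:
            return t_end
        t_end *= 2.0
    raise HorizonNotReachedError(
        f"I still rising at t = {t_end:g} after {MAX_DOUBLINGS} doublings")


def _analytic_metrics(wave, order: int) -> WaveMetrics:
    tm_raw = wave.peak_time
    if tm_raw <= 0.0:
        tm, Im, t_rn1 = 0.0, float(wave.I(0.0)), None
    else:
        tm, Im, t_rn1 = tm_raw, wave.peak_amplitude, tm_raw
    p = wave.params
    return WaveMetrics(Im=float(Im), tm=float(tm), t_Rn1=t_rn1,
                       R_final=float(wave.R_limit),
                       validity_max=float(validity_bound(p, wave.R_limit, M=order)))


def _refine_peak(wave, t_lo: float, t_hi: float) -> tuple[float, float]:
    res = minimize_scalar(lambda t: -wave.I(np.array(t)), bounds=(t_lo, t_hi),
                          method="bounded", options={"xatol": 1e-10 * max(t_hi, 1.0)})
    return float(res.x), float(-res.fun)


def compute_metrics(wave, rho: float | None = None, t_end: float | None = None) -> WaveMetrics:
    """Amplitude, time horizon, Rn = 1 crossing and validity maximum of a wave.

    ``wave`` is either an evaluable closed-form wave (:class:`RiccatiWaveM2`
    with D = 0, :class:`WaveM3`) — in which case the closed-form peak is used
    directly — or a sampled :class:`Trajectory`, in which case the peak comes
    from the grid (with parabolic refinement) and must lie inside the grid.
    """
    if isinstance(wave, RiccatiWaveM2):
        if wave.D == 0.0:
            return _analytic_metrics(wave, order=2)
        # general-D wave: locate the peak numerically on an auto-extended window
        t_end = _auto_t_end(wave, t_end or max(2.0 * abs(wave.C), 1.0))
        tm, Im = _refine_peak(wave, 0.0, t_end)
        if wave.I(0.0) >= Im or tm <= 0.0:
            tm, Im, t_rn1 = 0.0, float(wave.I(0.0)), None
        else:
            t_rn1 = tm
        return WaveMetrics(Im=Im, tm=tm, t_Rn1=t_rn1, R_final=float(wave.R_limit),
                           validity_max=float(validity_bound(wave.params, wave.R_limit, M=2)))
    if isinstance(wave, WaveM3):
        return _analytic_metrics(wave, order=3)
    if isinstance(wave, Trajectory):
        return _trajectory_metrics(wave, rho=rho)
    raise ParameterError(f"cannot compute metrics for {type(wave).__name__}")


def _trajectory_metrics(traj: Trajectory, rho: float | None = None) -> WaveMetrics:
    t, I = traj.t, traj.I
    k = int(np.argmax(I))
    if k == I.size - 1 and I[k] > I[0]:
        raise HorizonNotReachedError(
            "I is still rising at the end of the trajectory; re-solve with a larger t_end")
    if k == 0:
        tm, Im = 0.0, float(I[0])
    else:
        # parabolic refinement of the grid argmax
        y0, y1, y2 = I[k - 1], I[k], I[k + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        h = t[k] - t[k - 1]
        tm = float(t[k] + shift * h)
        Im = float(y1 - 0.25 * (y0 - y2) * shift)
    rho = rho if rho is not None else (traj.params.rho if traj.params else None)
    t_rn1 = None
    if rho is not None and tm > 0.0:
        sigma = growth_rate(traj)
        sign = np.sign(sigma)
        down = np.where((sign[:-1] > 0) & (sign[1:] <= 0))[0]
        if down.size:
            i = int(down[0])
            # linear interpolation of the sigma = 0 crossing
            s0, s1 = sigma[i], sigma[i + 1]
            t_rn1 = float(t[i] + (t[i + 1] - t[i]) * s0 / (s0 - s1))
    validity = None
    if traj.params is not None and traj.source in ("numeric-chain", "analytic-M2", "analytic-M3"):
        order = {"numeric-chain": traj.meta.get("M", 2), "analytic-M2": 2, "analytic-M3": 3}[traj.source]
        validity = float(np.max(validity_bound(traj.params, np.maximum(traj.R, 0.0), M=order)))
    return WaveMetrics(Im=Im, tm=tm, t_Rn1=t_rn1, R_final=float(traj.R[-1]),
                       validity_max=validity)


_SWEEPABLE = ("I0", "N", "tau", "rho")


def sensitivity_sweep(
    base: SIRParams,
    vary: str,
    values: Sequence[float],
    model: Literal["m2-d0", "m3"] = "m2-d0",
) -> list[WaveMetrics]:
    """Metrics of the closed-form wave as one parameter moves over a grid.

    For ``model="m2-d0"`` any of I0, N, tau, rho may vary (I0 and N adjust S0
    through conservation).  For the cubic family only I0, N and tau make
    sense, since rho is tied to the other parameters.
    """
    if vary not in _SWEEPABLE:
        raise ParameterError(f"vary must be one of {_SWEEPABLE}, got {vary!r}")
    if any(v <= 0 for v in values):
        raise ParameterError("sweep values must be positive")
    out = []
    for v in values:
        if model == "m2-d0":
            if vary == "I0":
                p = SIRParams.from_initial_spreaders(base.N, base.tau, base.rho, I0=v, R0=base.R0)
            elif vary == "N":
                p = SIRParams.from_initial_spreaders(v, base.tau, base.rho, I0=base.I0, R0=base.R0)
            elif vary == "tau":
                p = base.with_(tau=v)
            else:
                p = base.with_(rho=v)
            out.append(compute_metrics(RiccatiWaveM2(params=p, D=0.0, E=1.0)))
        elif model == "m3":
            if vary == "I0":
                wave = WaveM3(N=base.N, S0=base.N - v, tau=base.tau)
            elif vary == "N":
                wave = WaveM3(N=v, S0=v - base.I0, tau=base.tau)
            elif vary == "tau":
                wave = WaveM3(N=base.N, S0=base.S0, tau=v)
            else:
                raise ParameterError("rho is not free on the cubic family")
            out.append(compute_metrics(wave))
        else:
            raise ParameterError(f"unknown model {model!r}")
    return out


@dataclass(frozen=True)
class WaveTypeThresholds:
    """User-configurable cut-offs for 'large'/'small' tau and rho.

    The typology is qualitative; the shipped defaults bracket the basic
    scenario rates (~0.008) symmetrically.
    """

    tau_lo: float = 0.004
    tau_hi: float = 0.012
    rho_lo: float = 0.004
    rho_hi: float = 0.012

    def __post_init__(self) -> None:
        if not (self.tau_lo < self.tau_hi) or not (self.rho_lo < self.rho_hi):
            raise ConfigError("thresholds must satisfy tau_lo < tau_hi and rho_lo < rho_hi")


DEFAULT_THRESHOLDS = WaveTypeThresholds()


def classify_wave_type(tau: float, rho: float,
                       thresholds: WaveTypeThresholds = DEFAULT_THRESHOLDS) -> str:
    """Map (tau, rho) to a wave type A-E.

    A: high tau, low rho (large amplitude, short horizon);
    B: high tau, high rho; C: low tau, high rho; D: low tau, low rho;
    E: anything in the intermediate band.  Boundary values resolve away from
    E toward the adjacent corner, ties broken in the order A < B < C < D.
    """
    if tau <= 0 or rho <= 0:
        raise ParameterError("rates must be positive")
    hi_t, lo_t = tau >= thresholds.tau_hi, tau <= thresholds.tau_lo
    hi_r, lo_r = rho >= thresholds.rho_hi, rho <= thresholds.rho_lo
    if hi_t and lo_r:
        return "A"
    if hi_t and hi_r:
        return "B"
    if lo_t and hi_r:
        return "C"
    if lo_t and lo_r:
        return "D"
    return "E"
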