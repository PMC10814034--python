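"""The SIR compartment model used as a model of news spread.

A population of ``N`` individuals splits into potential spreaders of a piece
of news ``S`` (susceptible), active spreaders ``I`` and individuals no longer
interested ``R`` (removed), with constant transmission rate ``tau`` and
recovery rate ``rho``:

    dS/dt = -(tau/N) S I
    dI/dt =  (tau/N) S I - rho I
    dR/dt =  rho I

This module provides the parameter container, the adaptive numerical
integration of the full system (the ground-truth oracle the closed forms are
certified against), and the exact derived quantities: the logarithmic growth
rate sigma(t) = (1/I) dI/dt, the time-varying effective reproduction number
Rn(t) = 1 + sigma(t)/rho, and S as a function of R,
S = S(0) exp[-tau (R - R(0)) / (rho N)].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import IntegrationFailure, ParameterError

__all__ = [
    "SIRParams",
    "Trajectory",
    "integrate_sir",
    "growth_rate",
    "effective_reproduction_number",
    "susceptibles_from_R",
    "I_FLOOR_FRACTION",
]

#: Relative tolerance of the adaptive integrator.  The numerical oracle must
#: sit far below the truncation error of the closed forms it certifies.
INTEGRATOR_RTOL = 1e-9
#: Absolute tolerance as a fraction of N.
INTEGRATOR_ATOL_FRACTION = 1e-9
#: I below this fraction of N is treated as extinct: sigma and Rn undefined.
I_FLOOR_FRACTION = 1e-12
#: Slack, as a fraction of N, allowed on the S0+I0+R0=N conservation check.
CONSERVATION_RTOL = 1e-9

TRAJECTORY_SOURCES = ("numeric-SIR", "numeric-chain", "analytic-M2", "analytic-M3")


@dataclass(frozen=True)
class SIRParams:
    """Parameters of one news wave.

    Parameters
    ----------
    N : float
        Population size (persons, > 0).
    tau : float
        Transmission rate (per time unit, > 0).
    rho : float
        Recovery rate (per time unit, > 0).
    S0, I0, R0 : float
        Initial compartment counts (persons, >= 0); must sum to ``N``.
    """

    N: float
    tau: float
    rho: float
    S0: float
    I0: float
    R0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.N > 0):
            raise ParameterError(f"population N must be positive, got {self.N}")
        # tau = 0 is admitted as the transmission-off limit (pure decay);
        # the closed-form families themselves require tau > 0.
        if not (self.tau >= 0):
            raise ParameterError(f"transmission rate tau must be non-negative, got {self.tau}")
        if not (self.rho > 0):
            raise ParameterError(f"recovery rate rho must be positive, got {self.rho}")
        for name in ("S0", "I0", "R0"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative, got {getattr(self, name)}")
        if abs(self.S0 + self.I0 + self.R0 - self.N) > CONSERVATION_RTOL * self.N:
            raise ParameterError(
                f"S0 + I0 + R0 = {self.S0 + self.I0 + self.R0} does not equal N = {self.N}"
            )

    @classmethod
    def from_initial_spreaders(
        cls, N: float, tau: float, rho: float, I0: float, R0: float = 0.0
    ) -> "SIRParams":
        """Build params with S0 filled in from conservation, S0 = N - I0 - R0."""
        return cls(N=N, tau=tau, rho=rho, S0=N - I0 - R0, I0=I0, R0=R0)

    @property
    def effective_S0(self) -> float:
        """S(0)* = S(0) exp[tau R(0) / (rho N)].

        The closed forms assume R(0) = 0; a non-zero R(0) is folded into the
        susceptible pool through this substitution, after which the shifted
        R' = R - R(0) starts at zero.
        """
        return self.S0 * float(np.exp(self.tau * self.R0 / (self.rho * self.N)))

    @property
    def sigma0(self) -> float:
        """Initial growth rate sigma(0) = tau S(0)/N - rho."""
        return self.tau * self.S0 / self.N - self.rho

    @property
    def Rn0(self) -> float:
        """Initial effective reproduction number Rn(0) = 1 + sigma(0)/rho."""
        return 1.0 + self.sigma0 / self.rho

    def with_(self, **kwargs) -> "SIRParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Trajectory:
    """Sampled wave: compartment counts on an ordered time grid.

    ``source`` records provenance: full SIR integration, truncated-chain
    integration, or one of the closed-form families.
    """

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    source: str
    params: SIRParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("t", "S", "I", "R"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.source not in TRAJECTORY_SOURCES:
            raise ParameterError(
                f"unknown trajectory source {self.source!r}; expected one of {TRAJECTORY_SOURCES}"
            )
        if self.t.ndim != 1 or any(getattr(self, k).shape != self.t.shape for k in "SIR"):
            raise ParameterError("t, S, I, R must be 1-d arrays of equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ParameterError("time grid must be strictly increasing")
        if self.params is not None:
            N = self.params.N
            eps = 1e-6 * N
            for name in ("I", "R"):
                if np.any(getattr(self, name) < -eps):
                    raise ParameterError(f"compartment {name} below -{eps:g} (negative beyond slack)")
            if np.any(self.S < -eps):
                if self.source == "numeric-SIR":
                    raise ParameterError("compartment S negative beyond slack")
                # chain/analytic S is a first-order reconstruction; outside the
                # Taylor validity range it can go negative — report, don't die.
                warnings.warn(
                    f"{self.source} trajectory has S < 0: first-order S(R) used outside "
                    "its validity range (check validity_bound)", RuntimeWarning, stacklevel=3)
            if self.source == "numeric-SIR":
                drift = np.max(np.abs(self.S + self.I + self.R - N))
                if drift > 1e-6 * N:
                    raise ParameterError(f"conservation violated: max |S+I+R-N| = {drift:g}")
            if np.any(np.diff(self.R) < -1e-9 * N):
                raise ParameterError("R must be non-decreasing along t")

    @property
    def n_points(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        """DataFrame with columns t, S, I, R, sigma, Rn (sigma/Rn NaN where undefined)."""
        sigma = growth_rate(self)
        if self.params is not None:
            with np.errstate(invalid="ignore"):
                Rn = 1.0 + sigma / self.params.rho
        else:
            Rn = np.full_like(sigma, np.nan)
        return pd.DataFrame({"t": self.t, "S": self.S, "I": self.I, "R": self.R,
                             "sigma": sigma, "Rn": Rn})

    def write_csv(self, path: str | Path) -> None:
        """RFC-4180 CSV with header t,S,I,R,sigma,Rn; undefined sigma/Rn as empty fields."""
        self.to_frame().to_csv(path, index=False, float_format="%.10g", na_rep="")

    def write_json(self, path: str | Path) -> None:
        frame = self.to_frame()
        payload = {
            "source": self.source,
            "params": None if self.params is None else vars(self.params).copy()
            if not hasattr(self.params, "__dataclass_fields__")
            else {k: getattr(self.params, k) for k in self.params.__dataclass_fields__},
            "tolerances": {
                "integrator_rtol": INTEGRATOR_RTOL,
                "integrator_atol_fraction": INTEGRATOR_ATOL_FRACTION,
                "I_floor_fraction": I_FLOOR_FRACTION,
            },
            "meta": self.meta,
            "columns": {c: [None if np.isnan(v) else v for v in frame[c]] for c in frame.columns},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def integrate_sir(params: SIRParams, t_end: float, n_points: int = 2001) -> Trajectory:
    """Integrate the full SIR system and sample it on a uniform grid.

    Uses an adaptive stiff-capable solver (LSODA) at rtol 1e-9 so that the
    result can serve as an oracle for the closed-form solutions.
    """
    if not t_end > 0:
        raise ParameterError(f"t_end must be positive, got {t_end}")
    if n_points < 2:
        raise ParameterError(f"n_points must be >= 2, got {n_points}")
    N, tau, rho = params.N, params.tau, params.rho

    def rhs(t, y):
        S, I, R = y
        inf = tau / N * S * I
        return (-inf, inf - rho * I, rho * I)

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        (params.S0, params.I0, params.R0),
        method="LSODA",
        rtol=INTEGRATOR_RTOL,
        atol=min(INTEGRATOR_ATOL_FRACTION * N, 1e-6),
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationFailure(f"SIR integration failed near t = {sol.t[-1]:g}: {sol.message}")
    t = np.linspace(0.0, t_end, n_points)
    y = sol.sol(t)
    if not np.all(np.isfinite(y)):
        bad = t[np.argmax(~np.all(np.isfinite(y), axis=0))]
        raise IntegrationFailure(f"non-finite SIR state at t = {bad:g}")
    return Trajectory(t=t, S=y[0], I=y[1], R=y[2], source="numeric-SIR", params=params)


def growth_rate(trajectory: Trajectory) -> np.ndarray:
    """sigma(t) = d ln I / dt by central differences of ln I.

    Differencing ln I (rather than I) is exact for exponential growth/decay,
    which is the regime where sigma matters.  Grid points with I below the
    extinction floor are returned as NaN; endpoints use one-sided differences.
    """
    I = trajectory.I
    N = trajectory.params.N if trajectory.params is not None else max(float(np.max(I)), 1.0)
    floor = I_FLOOR_FRACTION * N
    valid = I > floor
    sigma = np.full(I.shape, np.nan)
    if not np.any(valid):
        warnings.warn("I is zero (or below floor) everywhere; growth rate undefined",
                      RuntimeWarning, stacklevel=2)
        return sigma
    # np.gradient handles non-uniform grids and one-sided endpoints at 2nd order.
    logI = np.where(valid, np.log(np.where(valid, I, 1.0)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sigma = np.gradient(logI, trajectory.t, edge_order=2)
    sigma[~valid] = np.nan
    return sigma


def effective_reproduction_number(trajectory: Trajectory, rho: float) -> np.ndarray:
    """Rn(t) = 1 + sigma(t)/rho; Rn < 1 exactly where I is decreasing."""
    if rho <= 0:
        raise ParameterError(f"rho must be positive, got {rho}")
    with np.errstate(invalid="ignore"):
        return 1.0 + growth_rate(trajectory) / rho


def susceptibles_from_R(params: SIRParams, R, linearized: bool = False):
    """S as an exact function of R (or its first-order Taylor truncation).

    Exact:       S = S(0) exp[-tau (R - R(0)) / (rho N)]
    Linearized:  S = S(0) [1 - tau (R - R(0)) / (rho N)]

    The two agree to second order in x = tau (R - R(0)) / (rho N).  A negative
    linearized value signals use outside the validity range of the truncation
    and triggers a warning, not an error.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < params.R0 - CONSERVATION_RTOL * params.N):
        raise ParameterError("R must be >= R(0)")
    x = params.tau * (R - params.R0) / (params.rho * params.N)
    if linearized:
        S = params.S0 * (1.0 - x)
        if np.any(S < 0):
            warnings.warn("linearized S(R) is negative: outside the validity range",
                          RuntimeWarning, stacklevel=2)
        return S if S.shape else float(S)
    S = params.S0 * np.exp(-x)
    return S if S.shape else float(S)
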