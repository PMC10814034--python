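"""Reduction of the SIR system to a chain of polynomial ODEs.

Eliminating S and I leaves one equation for the removed compartment,

    dR/dt = rho [N - R - S(0) exp(-tau R / (rho N))],

whose exponential can be truncated at Taylor order M, giving the polynomial
chain  dR/dt = sum_{j=0}^{M} alpha_j R^j  with

    alpha_0 = rho [N - S(0)],
    alpha_1 = tau S(0)/N - rho,
    alpha_j = -(-1)^j / j! * tau^j S(0) / (rho^{j-1} N^j),   j >= 2,

so alpha_j < 0 for even j >= 2 and alpha_j > 0 for odd j >= 3.  The Lagrange
remainder of the truncation is controlled by the validity bound
(e / (M+1)!) * x^{M+1} with x = tau R / (rho N).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core_model import INTEGRATOR_RTOL, SIRParams, Trajectory
from .exceptions import IntegrationFailure, OrderError, TruncationBreakdownError

__all__ = [
    "ChainCoefficients",
    "compute_alphas",
    "truncated_rhs",
    "taylor_ratio",
    "validity_bound",
    "integrate_chain",
    "DEFAULT_ORDER",
    "VALIDITY_THRESHOLD",
]

#: Default truncation order; M = 2 is the primary working order (the Riccati case).
DEFAULT_ORDER = 2
#: Operationalization of "much smaller than 1" for the validity bound; values
#: above it draw a warning, not an error (a bound of ~0.113 is still usable).
VALIDITY_THRESHOLD = 0.1


@dataclass(frozen=True)
class ChainCoefficients:
    """Coefficients alpha_0..alpha_M of the truncated polynomial chain."""

    M: int
    alpha: np.ndarray
    params: SIRParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        if self.alpha.shape != (self.M + 1,):
            raise OrderError(f"expected {self.M + 1} coefficients, got {self.alpha.shape}")


def compute_alphas(params: SIRParams, M: int = DEFAULT_ORDER) -> ChainCoefficients:
    """Coefficients of the order-M truncation.

    A non-zero R(0) is folded in through the effective S(0)* substitution so
    that the chain always starts from (shifted) R = 0.
    """
    if M < 2:
        raise OrderError(f"truncation order M must be >= 2, got {M}")
    N, tau, rho = params.N, params.tau, params.rho
    S0 = params.effective_S0
    alpha = np.empty(M + 1)
    alpha[0] = rho * (N - S0)
    alpha[1] = tau * S0 / N - rho
    for j in range(2, M + 1):
        alpha[j] = -((-1.0) ** j) / math.factorial(j) * tau**j * S0 / (rho ** (j - 1) * N**j)
    return ChainCoefficients(M=M, alpha=alpha, params=params)


def truncated_rhs(R, coeffs: ChainCoefficients):
    """Evaluate sum_j alpha_j R^j in nested (Horner) form.

    Horner evaluation keeps the sum stable although the coefficient
    magnitudes span many orders of magnitude.
    """
    R = np.asarray(R, dtype=float)
    out = np.zeros_like(R)
    for a in coeffs.alpha[::-1]:
        out = out * R + a
    return out if out.shape else float(out)


def taylor_ratio(params: SIRParams, R):
    """The raw expansion variable x = tau R / (rho N)."""
    R = np.asarray(R, dtype=float)
    x = params.tau * R / (params.rho * params.N)
    return x if x.shape else float(x)


def validity_bound(params: SIRParams, R, M: int = DEFAULT_ORDER, warn: bool = False):
    """Lagrange-remainder bound (e/(M+1)!) x^{M+1} of the order-M truncation.

    The truncation is trustworthy while this is small; ``warn=True`` emits a
    warning when the bound exceeds :data:`VALIDITY_THRESHOLD`.
    """
    if np.any(np.asarray(R) < 0):
        raise OrderError("R must be non-negative")
    x = np.asarray(taylor_ratio(params, R))
    bound = math.e / math.factorial(M + 1) * x ** (M + 1)
    if warn and np.any(bound > VALIDITY_THRESHOLD):
        warnings.warn(
            f"validity bound exceeds {VALIDITY_THRESHOLD}: truncation at order {M} "
            "may be unreliable", RuntimeWarning, stacklevel=2)
    return bound if bound.shape else float(bound)


def integrate_chain(coeffs: ChainCoefficients, t_end: float, n_points: int = 2001) -> Trajectory:
    """Numerically integrate the truncated chain from R(0) = 0.

    I is recovered as (1/rho) dR/dt = (1/rho) * truncated_rhs(R); S from the
    first-order S(R) relation.  Serves as a secondary oracle: the closed forms
    must agree with this to within the integrator tolerance.
    """
    if not t_end > 0:
        raise OrderError(f"t_end must be positive, got {t_end}")
    params = coeffs.params
    N = params.N

    def rhs(t, y):
        return (truncated_rhs(y[0], coeffs),)

    def blow_up(t, y):
        return y[0] - N

    blow_up.terminal = True

    sol = solve_ivp(
        rhs, (0.0, t_end), (0.0,), method="LSODA",
        rtol=INTEGRATOR_RTOL, atol=min(1e-9 * N, 1e-6),
        dense_output=True, events=blow_up,
    )
    if sol.t_events[0].size:
        raise TruncationBreakdownError(
            f"R reached N at t = {sol.t_events[0][0]:g}: the order-{coeffs.M} truncation "
            "broke down; check validity_bound along the trajectory")
    if not sol.success:
        raise IntegrationFailure(f"chain integration failed: {sol.message}")
    t = np.linspace(0.0, t_end, n_points)
    R = sol.sol(t)[0]
    I = truncated_rhs(R, coeffs) / params.rho
    # first-order S(R), written against the effective S(0)* (R measured from R(0))
    S = params.effective_S0 * (1.0 - params.tau * R / (params.rho * N))
    return Trajectory(t=t, S=np.asarray(S), I=I, R=R, source="numeric-chain", params=params,
                      meta={"M": coeffs.M})
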