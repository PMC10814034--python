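"""Closed-form wave families: exactness, limits, constants, negative controls."""

import numpy as np
import pytest

from sirwaves import (
    RiccatiWaveM2,
    SIRParams,
    WaveM3,
    compute_alphas,
    correction_at_minus_C,
    peak_amplitude_m2,
    peak_time_m2,
    residual_m2,
    residual_m3,
    rho_m3,
    solve_m2,
    solve_m3,
    theta,
)
from sirwaves.exceptions import (
    AssumptionViolatedError,
    ConstantsInfeasibleError,
    NoWaveError,
    ParameterError,
    UnsupportedBranchError,
)

FIG9 = dict(N=1e6, S0=9e5, tau=0.009)


class TestTheta:
    def test_transmission_off_gives_rho(self):
        p = SIRParams(N=1e4, tau=0.0, rho=0.07, S0=9e3, I0=1e3)
        assert theta(p) == pytest.approx(0.07, rel=1e-12)

    def test_whole_population_susceptible(self):
        p = SIRParams(N=1e4, tau=0.02, rho=0.05, S0=1e4, I0=0.0)
        assert theta(p) == pytest.approx(abs(0.02 - 0.05), rel=1e-12)

    def test_discriminant_identity(self, basic_params):
        # theta^2 = alpha1^2 - 4 alpha0 alpha2 exactly
        a0, a1, a2 = compute_alphas(basic_params, 2).alpha
        assert theta(basic_params) ** 2 == pytest.approx(a1**2 - 4 * a0 * a2, rel=1e-12)


class TestRiccatiWaveM2:
    def test_starts_at_zero(self, basic_params):
        for D in (0.0, 0.1, 1e4):
            wave = RiccatiWaveM2(params=basic_params, D=D, E=1.0)
            assert abs(wave.R(np.array([0.0]))[0]) <= 1e-9 * basic_params.N

    def test_large_t_limit(self, basic_params, basic_grid):
        a0, a1, a2 = compute_alphas(basic_params, 2).alpha
        th = theta(basic_params)
        wave = RiccatiWaveM2(params=basic_params)
        expected = -a1 / (2 * a2) - th / (2 * a2)
        assert wave.R(np.array([1e7]))[0] == pytest.approx(expected, rel=1e-9)
        assert wave.R_limit == pytest.approx(expected, rel=1e-12)

    def test_pulse_is_nonnegative(self, basic_params, basic_grid):
        traj = solve_m2(basic_params, basic_grid)
        assert np.all(traj.I >= 0)

    def test_agreement_with_chain_equivalent_forms(self, basic_params, basic_grid):
        # centred-tanh (growing) and logistic (decaying) branches both solve
        # the same Riccati equation: residuals certify each
        assert residual_m2(basic_params, 0.0, 1.0, basic_grid) < 1e-5
        decaying = basic_params.with_(rho=0.075)
        t = np.linspace(0.0, 200.0, 40_001)
        assert residual_m2(decaying, 0.0, 1.0, t) < 1e-5

    def test_d_nonzero_residual(self, basic_params, basic_grid):
        # admissible constants: alpha1 > 0 and D/E below theta/(-2 alpha2)
        assert residual_m2(basic_params, 1e5, 1.0, basic_grid) < 1e-5
        assert residual_m2(basic_params, 0.1, 1.0, basic_grid) < 1e-5

    def test_d_to_zero_converges_to_canonical_branch(self, basic_params):
        t = np.linspace(0.0, 60_000.0, 101)
        base = RiccatiWaveM2(params=basic_params, D=0.0, E=1.0)
        close = RiccatiWaveM2(params=basic_params, D=1e-6, E=1.0)
        scale = np.max(base.R(t))
        assert np.max(np.abs(base.R(t) - close.R(t))) / scale < 1e-9

    def test_infeasible_constants_rejected(self, basic_params):
        a0, a1, a2 = compute_alphas(basic_params, 2).alpha
        sup = theta(basic_params) / (-2 * a2)
        with pytest.raises(ConstantsInfeasibleError):
            RiccatiWaveM2(params=basic_params, D=5 * sup, E=1.0)

    def test_unsupported_branch(self, basic_params):
        with pytest.raises(UnsupportedBranchError):
            RiccatiWaveM2(params=basic_params, D=1.0, E=0.0)
        with pytest.raises(ParameterError):
            RiccatiWaveM2(params=basic_params, D=0.0, E=0.0)

    def test_peak_closed_forms_match_numerical_maximum(self, basic_params):
        from scipy.optimize import minimize_scalar

        wave = RiccatiWaveM2(params=basic_params)
        tm = peak_time_m2(basic_params)
        res = minimize_scalar(lambda t: -wave.I(np.array([t]))[0],
                              bounds=(0.5 * tm, 1.5 * tm), method="bounded",
                              options={"xatol": 1e-6 * tm})
        assert tm == pytest.approx(res.x, rel=1e-6)
        assert peak_amplitude_m2(basic_params) == pytest.approx(-res.fun, rel=1e-6)

    def test_I_matches_finite_difference_of_R(self, basic_params):
        # I = (1/rho) dR/dt also for the D != 0 branch
        wave = RiccatiWaveM2(params=basic_params, D=1e4, E=1.0)
        t = np.linspace(0.0, 60_000.0, 40_001)
        h = t[1] - t[0]
        R = wave.R(t)
        dR = (R[:-4] - 8 * R[1:-3] + 8 * R[3:-1] - R[4:]) / (12 * h)
        I_inner = wave.I(t)[2:-2]
        assert np.max(np.abs(I_inner - dR / basic_params.rho)) / np.max(I_inner) < 1e-8


class TestCorrectionBounds:
    def test_d0_reference(self, basic_params):
        cb = correction_at_minus_C(basic_params, 0.0, 1.0)
        assert cb.value == cb.d0_reference

    def test_supremum_attains_upper_bound(self, basic_params):
        a0, a1, a2 = compute_alphas(basic_params, 2).alpha
        sup = theta(basic_params) / (-2 * a2)
        cb = correction_at_minus_C(basic_params, sup, 1.0)
        assert cb.value == pytest.approx(cb.upper_bound, rel=1e-12)

    def test_admissible_ratio_strictly_between(self, basic_params):
        a0, a1, a2 = compute_alphas(basic_params, 2).alpha
        sup = theta(basic_params) / (-2 * a2)
        cb = correction_at_minus_C(basic_params, 0.5 * sup, 1.0)
        assert cb.d0_reference < cb.value < cb.upper_bound

    def test_requires_growing_wave(self, basic_params):
        with pytest.raises(AssumptionViolatedError):
            correction_at_minus_C(basic_params.with_(rho=0.075), 1.0, 1.0)
        with pytest.raises(AssumptionViolatedError):
            correction_at_minus_C(basic_params, 1.0, -1.0)


class TestWaveM3:
    def test_rho_is_derived(self):
        wave = WaveM3(**FIG9)
        assert wave.rho == pytest.approx(0.009 * (1 - 9e5 / 3e6), rel=1e-12)
        assert rho_m3(**FIG9) == wave.rho

    def test_initial_conditions(self):
        wave = WaveM3(**FIG9)
        assert wave.R(np.array([0.0]))[0] == pytest.approx(0.0, abs=1e-9 * wave.N)
        # I(0) = N - S0 = 1e5 for the basic dissipative wave
        assert wave.I(np.array([0.0]))[0] == pytest.approx(1e5, rel=1e-12)

    def test_large_t_limit(self):
        wave = WaveM3(**FIG9)
        assert wave.R_limit == pytest.approx(1e6 - 9e5 / 3, rel=1e-12)  # 7e5
        assert wave.R(np.array([1e5]))[0] == pytest.approx(wave.R_limit, rel=1e-9)

    def test_residual_certifies_exactness(self):
        t = np.linspace(0.0, 3000.0, 40_001)
        assert residual_m3(1e6, 9e5, 0.009, t) < 1e-5

    def test_perturbed_constraint_breaks_residual(self):
        # negative control: the rho relation is necessary, +10% destroys it
        t = np.linspace(0.0, 3000.0, 40_001)
        assert residual_m3(1e6, 9e5, 0.009, t, rho=1.1 * rho_m3(1e6, 9e5, 0.009)) > 1e-3

    def test_degenerate_limit_near_whole_population(self):
        # S0 -> N: the wave degenerates to (nearly) nothing on any fixed window
        t = np.linspace(0.0, 100.0, 2001)
        wave = WaveM3(N=1e6, S0=1e6 - 1e-6, tau=0.009)
        assert np.max(np.abs(wave.R(t))) < 1e-3
        assert np.max(wave.I(t)) < 1e-3
        # one seed spreader: still certifiable (alpha0 no longer ~0)
        assert residual_m3(1e6, 1e6 - 1.0, 0.009, t) < 1e-5

    def test_whole_population_rejected(self):
        with pytest.raises(NoWaveError):
            WaveM3(N=1e6, S0=1e6, tau=0.009)

    def test_I_is_rho_inverse_dR_dt(self):
        wave = WaveM3(**FIG9)
        t = np.linspace(0.0, 3000.0, 40_001)
        h = t[1] - t[0]
        R = wave.R(t)
        dR = (R[:-4] - 8 * R[1:-3] + 8 * R[3:-1] - R[4:]) / (12 * h)
        I_inner = wave.I(t)[2:-2]
        assert np.max(np.abs(I_inner - dR / wave.rho)) / np.max(I_inner) < 1e-5

    def test_matches_chain_integration(self):
        from sirwaves import integrate_chain

        wave = WaveM3(**FIG9)
        t_end = wave.peak_time + 6.0 / wave.growth_scale
        grid = np.linspace(0.0, t_end, 20_001)
        chain = integrate_chain(compute_alphas(wave.params, 3), t_end, 20_001)
        err = np.max(np.abs(chain.R - wave.R(grid))) / np.max(wave.R(grid))
        assert err < 1e-6

    def test_monotone_decay_for_large_initial_spreaders(self):
        # S0 <= 3N/4 (large I(0)): the wave only decays, horizon 0
        wave = WaveM3(N=1e6, S0=5e5, tau=0.009)
        t = np.linspace(0.0, 2000.0, 2001)
        assert wave.peak_time == 0.0
        assert np.all(np.diff(wave.I(t)) < 0)

    def test_trajectory_source_label(self):
        traj = solve_m3(1e6, 9e5, 0.009, np.linspace(0, 100, 11))
        assert traj.source == "analytic-M3"
        assert traj.params.rho == rho_m3(1e6, 9e5, 0.009)
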