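"""Self-guiding machinery: filters, derived low-frequency state, apparent
friction, eta scaling, and guiding-factor conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgsim.errors import ConfigurationError, DomainError, InvalidInputError
from sgsim.guiding import (
    FrictionAccumulators,
    GuidingParams,
    LocalAverageState,
    Mode,
    balanced_force_factor,
    balanced_momentum_factor,
    conservation_scaling_eta,
    derive_low_frequency_state,
    equivalent_force_factor,
    gle_nu,
    guiding_force,
    local_average_update,
    update_friction_estimate,
    update_position_and_energy_averages,
)


class TestLocalAverage:
    def test_single_step_arithmetic(self):
        assert local_average_update(0.0, 1.0, 0.001, 0.2) == pytest.approx(0.005)

    def test_constant_signal_is_fixed_point(self):
        x = 3.7
        for _ in range(100):
            x = local_average_update(x, 3.7, 0.01, 0.2)
        assert x == pytest.approx(3.7, abs=1e-14)

    def test_dt_equal_tl_returns_current(self):
        assert local_average_update(5.0, -2.0, 0.2, 0.2) == -2.0

    def test_dt_above_tl_rejected(self):
        with pytest.raises(ConfigurationError):
            local_average_update(0.0, 1.0, 0.3, 0.2)

    def test_recursion_matches_explicit_convolution(self):
        """The recursive filter equals the discrete exponential kernel
        (dt/t_L)(1 - dt/t_L)^k applied to the signal history."""
        dt, t_L, n = 0.001, 0.05, 10_000  # dt/t_L = 0.02
        t = np.arange(n) * dt
        signal = np.sin(2 * np.pi * t / 0.7) + 0.3 * np.sin(40 * t)
        avg = 0.0
        rec = np.empty(n)
        for k, s in enumerate(signal):
            avg = local_average_update(avg, s, dt, t_L)
            rec[k] = avg
        w = dt / t_L
        weights = w * (1 - w) ** np.arange(n)
        conv = np.convolve(signal, weights)[:n]
        assert np.max(np.abs(rec - conv)) / np.max(np.abs(conv)) < 1e-10


class TestPositionEnergyAverages:
    def test_constant_inputs_stay_constant(self):
        r = np.ones((2, 3))
        st_ = LocalAverageState.cold_start(r, 5.0)
        for _ in range(50):
            st_ = update_position_and_energy_averages(st_, r, 5.0, 0.001, 0.2)
        assert np.allclose(st_.r_avg, r) and np.allclose(st_.r_avg2, r)
        assert st_.E_avg == pytest.approx(5.0) and st_.E_avg2 == pytest.approx(5.0)

    def test_single_step_moves_by_fraction(self):
        r0 = np.zeros((1, 3))
        st_ = LocalAverageState.cold_start(r0, 0.0)
        r1 = np.array([[1.0, 0, 0]])
        st_ = update_position_and_energy_averages(st_, r1, 2.0, 0.001, 0.2)
        assert st_.r_avg[0, 0] == pytest.approx(0.005)
        assert st_.E_avg == pytest.approx(0.01)
        # the doubly filtered average chases the just-updated single average
        assert st_.E_avg2 == pytest.approx(0.005 * 0.01)

    def test_shape_mismatch_rejected(self):
        st_ = LocalAverageState.cold_start(np.zeros((2, 3)), 0.0)
        with pytest.raises(InvalidInputError):
            update_position_and_energy_averages(st_, np.zeros((3, 3)), 0.0,
                                                0.001, 0.2)


class TestLowFrequencyState:
    def test_cold_start_gives_zero_momentum_and_curvature(self):
        r = np.full((2, 3), 1.5)
        m = np.array([1.0, 2.0])
        p_lf, p, F_lf, F_lf2 = derive_low_frequency_state(
            r, r.copy(), r.copy(), np.zeros((2, 3)), m, 0.001, 0.2
        )
        assert np.all(p_lf == 0) and np.all(F_lf2 == 0)

    def test_flf_identity(self, rng):
        r = rng.normal(size=(3, 3))
        ra, ra2 = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        pp = rng.normal(size=(3, 3))
        m = np.array([1.0, 2.0, 39.9])
        t_L = 0.2
        p_lf, p, F_lf, _ = derive_low_frequency_state(r, ra, ra2, pp, m, 0.001, t_L)
        assert np.allclose(F_lf, (p - p_lf) / t_L, atol=1e-12)

    def test_uniform_motion_steady_state_and_contraction(self):
        """For constant velocity, p_lf converges to m*v geometrically with
        per-step contraction (1 - dt/t_L); the discrete fixed point is
        m*v*(1 - dt/t_L)."""
        m, v, dt, t_L = 2.0, 1.3, 0.001, 0.2
        delta = dt / t_L
        r_avg = np.zeros((1, 3))
        p_prev = np.zeros((1, 3))
        target = m * v * (1 - delta)
        devs = []
        for k in range(1, 8000):
            r = np.array([[v * k * dt, 0.0, 0.0]])
            r_avg = (1 - delta) * r_avg + delta * r
            p_lf, _, _, _ = derive_low_frequency_state(
                r, r_avg, r_avg, p_prev, np.array([m]), dt, t_L
            )
            devs.append(p_lf[0, 0] - target)
            p_prev = p_lf
        devs = np.array(devs)
        assert abs(devs[-1]) < 1e-9 * m * v
        ratios = devs[1001:2000] / devs[1000:1999]
        assert np.allclose(ratios, 1 - delta, atol=1e-9)

    def test_zero_dt_rejected(self):
        with pytest.raises(InvalidInputError):
            derive_low_frequency_state(
                np.zeros((1, 3)), np.zeros((1, 3)), np.zeros((1, 3)),
                np.zeros((1, 3)), np.array([1.0]), 0.0, 0.2
            )


class TestFrictionEstimate:
    def test_exact_proportionality_recovered(self, rng):
        """A stream with F_lf - F_lf2 = -3 p_lf recovers xi = 3 (1/ps)."""
        acc = FrictionAccumulators.cold_start(1)
        dt, t_avg = 0.001, 0.1
        for _ in range(10 * int(t_avg / dt)):
            p = rng.normal(size=(1, 3))
            acc = update_friction_estimate(acc, -3.0 * p, np.zeros((1, 3)), p,
                                           dt, t_avg)
        assert acc.xi[0] == pytest.approx(3.0, abs=1e-8)

    def test_zero_momentum_guard(self):
        acc = FrictionAccumulators.cold_start(2)
        z = np.zeros((2, 3))
        acc = update_friction_estimate(acc, z, z, z, 0.001, 0.1)
        assert np.all(acc.xi == 0)

    def test_uncorrelated_noise_gives_zero_friction(self, rng):
        """White force deviations uncorrelated with p_lf average to xi ~ 0."""
        acc = FrictionAccumulators.cold_start(1)
        dt, t_avg, n = 0.001, 0.1, 100_000
        for _ in range(n):
            acc = update_friction_estimate(
                acc, rng.normal(size=(1, 3)), np.zeros((1, 3)),
                rng.normal(size=(1, 3)), dt, t_avg,
            )
        # SE of the filtered covariance estimate: sqrt(delta/2) per component
        se = np.sqrt((dt / t_avg) / 2 / 3)
        assert abs(acc.xi[0]) < 3 * se


class TestGuidingForce:
    def test_zero_factors_give_zero(self, rng):
        g = guiding_force(0.0, 0.0, np.ones(2), rng.normal(size=(2, 3)),
                          rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        assert np.all(g == 0)

    def test_momentum_term(self):
        g = guiding_force(1.0, 0.0, np.array([2.0]),
                          np.array([[1.0, 0, 0]]), np.zeros((1, 3)),
                          np.zeros((1, 3)))
        assert np.allclose(g, [[2.0, 0, 0]])

    def test_force_term(self):
        g = guiding_force(0.0, -0.2, np.zeros(1), np.zeros((1, 3)),
                          np.array([[5.0, 0, 0]]), np.zeros((1, 3)))
        assert np.allclose(g, [[-1.0, 0, 0]])


class TestEtaScaling:
    def test_zero_guiding_gives_zero_eta(self, rng):
        eta = conservation_scaling_eta(
            np.zeros((2, 3)), rng.normal(size=(2, 3)), rng.normal(size=(2, 3)),
            5.0, np.ones(2), 0.001,
        )
        assert np.all(eta == 0)

    def test_arithmetic_example(self):
        # arrange p0 = m v (f = -g, gamma = 0) with g.p0 = 1, p0.p0 = 10
        dt = 0.001
        v = np.array([[np.sqrt(10.0), 0, 0]])
        g = np.array([[1 / np.sqrt(10.0), 0, 0]])
        eta = conservation_scaling_eta(g, v, -g, 0.0, np.ones(1), dt)
        assert eta[0] == pytest.approx(2.0 / (20.0 - dt), rel=1e-12)

    def test_degenerate_p0_guard_warns(self):
        g = np.array([[1.0, 0, 0]])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            eta = conservation_scaling_eta(g, np.zeros((1, 3)), -g, 0.0,
                                           np.ones(1), 0.001)
        assert eta[0] == 0.0

    def test_eta_cancels_guiding_work_over_one_step(self):
        """With eta applied, the kinetic-energy change due to the guiding
        force vanishes to O(dt^2) on a free particle."""
        m, dt = np.ones(1), 1e-3
        v = np.array([[2.0, 1.0, 0.0]])
        g = np.array([[0.5, -0.3, 0.0]])
        f = np.zeros((1, 3))
        eta = conservation_scaling_eta(g, v, f + g, 0.0, m, dt)
        a = eta[0] * dt / 2
        v_eta = ((1 - a) / (1 + a)) * v + (f + g) * dt / (m[:, None] * (1 + a))
        dke_with = 0.5 * m[0] * (np.sum(v_eta**2) - np.sum(v**2))
        v_plain = v + (f + g) * dt / m[:, None]
        dke_without = 0.5 * m[0] * (np.sum(v_plain**2) - np.sum(v**2))
        assert abs(dke_with) < 0.01 * abs(dke_without)


class TestBalancedFactors:
    def test_printed_correspondence(self):
        """lambda = -1 <-> mu = 0.3177 and lambda = +1 <-> mu = -0.3247 in
        the equal-enhancement convention; the bias-canceling factor has the
        opposite sign."""
        assert round(equivalent_force_factor(-1.0), 4) == 0.3177
        assert round(equivalent_force_factor(1.0), 4) == -0.3247
        assert balanced_force_factor(1.0) == pytest.approx(0.3247, abs=5e-5)

    def test_zero_is_fixed_point(self):
        assert balanced_force_factor(0.0) == 0.0
        assert balanced_momentum_factor(0.0) == 0.0

    @given(st.floats(-1.0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inverse_pair(self, lam):
        mu = balanced_force_factor(lam)
        assert balanced_momentum_factor(mu) == pytest.approx(lam, abs=1e-10)

    def test_balance_relation_satisfied(self):
        """mu_lambda solves the balance cubic u^3 - lambda*u - 1 = 0."""
        for lam in (-1.5, -0.5, 0.3, 1.0, 1.8):
            u = 1.0 + balanced_force_factor(lam)
            assert u**3 - lam * u - 1.0 == pytest.approx(0.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            balanced_force_factor(2.0)
        with pytest.raises(DomainError):
            balanced_momentum_factor(-1.0)

    def test_continuity_near_zero(self):
        lams = np.linspace(-0.01, 0.01, 21)
        mus = np.array([balanced_force_factor(l) for l in lams])
        assert np.all(np.abs(np.diff(mus)) < 1e-3)


class TestGleNu:
    @pytest.mark.parametrize("lam, nu", [(0.0, 0.0), (1.0, 1.0), (0.75, 0.5)])
    def test_values(self, lam, nu):
        assert gle_nu(lam) == pytest.approx(nu, abs=1e-14)

    @given(st.floats(-3.0, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip(self, lam):
        nu = gle_nu(lam)
        assert nu * (2 - nu) == pytest.approx(lam, abs=1e-13)

    def test_domain(self):
        with pytest.raises(DomainError):
            gle_nu(1.1)


class TestGuidingParamsValidation:
    def test_md_requires_zero_gamma(self):
        with pytest.raises(ConfigurationError):
            GuidingParams(mode=Mode.MD, gamma=1.0)

    def test_gle_requires_mu_zero_and_lambda_le_one(self):
        with pytest.raises(ConfigurationError):
            GuidingParams(mode=Mode.SGLD_GLE, gamma=1.0, mu=0.1)
        with pytest.raises(DomainError):
            GuidingParams(mode=Mode.SGLD_GLE, gamma=1.0, lambda_=1.2)

    def test_t_avg_default_is_ten_t_l(self):
        assert GuidingParams(t_L=0.3).t_avg == pytest.approx(3.0)
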