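"""Replica exchange: frequency factors, exchange probabilities, Metropolis
bookkeeping, and ladder drivers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sgsim.constants import KB
from sgsim.guiding import GuidingParams, Mode
from sgsim.integrators import IntegratorConfig
from sgsim.replica import (
    FrequencyFactors,
    ReplicaState,
    StageSpec,
    attempt_exchange,
    exchange_coefficients,
    exchange_probability_generalized,
    exchange_probability_legacy,
    frequency_factors,
    generalized_log_ratio,
    legacy_log_ratio,
    run_rxsgld,
)
from sgsim.systems import build_sdw_system

finite = st.floats(-50.0, 50.0, allow_nan=False)


class TestFrequencyFactors:
    def test_zero_guiding_collision_factors_unity(self, rng):
        n = 5
        f = rng.normal(size=(n, 3))
        p = rng.normal(size=(n, 3))
        ff = frequency_factors(f, f * 0.5, np.zeros((n, 3)), np.zeros((n, 3)),
                               p, p * 0.4, 10.0)
        assert ff.chi_lf == pytest.approx(1.0)
        assert ff.chi_hf == pytest.approx(1.0)

    def test_md_self_projection(self, rng):
        """With gamma = 0, no guiding, and fully converged averages, the
        low-frequency energy factor is the self-projection of f_avg."""
        n = 4
        f = rng.normal(size=(n, 3))
        ff = frequency_factors(f, f, np.zeros((n, 3)), np.zeros((n, 3)),
                               np.zeros((n, 3)), np.zeros((n, 3)), 0.0)
        assert ff.lambda_lf == pytest.approx(1.0)

    def test_half_friction_guiding(self, rng):
        """g_avg = gamma p_avg / 2 gives chi_lf = 1/2."""
        n = 3
        gamma = 4.0
        p_lf = rng.normal(size=(n, 3))
        g_avg = gamma * p_lf / 2
        ff = frequency_factors(rng.normal(size=(n, 3)), rng.normal(size=(n, 3)),
                               g_avg, g_avg, p_lf, p_lf, gamma)
        assert ff.chi_lf == pytest.approx(0.5)

    def test_degenerate_denominator_warns(self):
        z = np.zeros((2, 3))
        with pytest.warns(RuntimeWarning):
            ff = frequency_factors(z, z, z, z, z, z, 1.0)
        assert ff.lambda_lf == 1.0


class TestExchangeCoefficients:
    def test_no_guiding(self):
        l, h = exchange_coefficients(StageSpec(0, 274.0), FrequencyFactors())
        assert l == 0.0
        assert h == pytest.approx(1.0 / (KB * 274.0))

    def test_cancellation(self):
        ff = FrequencyFactors(1.3, 1.3, 1.0, 1.0)
        l, _ = exchange_coefficients(StageSpec(0, 300.0), ff)
        assert l == pytest.approx(0.0)

    def test_arithmetic(self):
        ff = FrequencyFactors(1.2, 1.0, 1.0, 1.0)
        l, h = exchange_coefficients(StageSpec(0, 274.0), ff)
        assert l == pytest.approx(0.2 / (KB * 274.0))


class TestExchangeProbabilities:
    def test_identical_coefficients_always_accept(self):
        pi = exchange_probability_legacy(1.0, 0.5, -2.0, 0.1, 3.0, 1.0, 3.0, 1.0)
        assert pi == 1.0

    def test_legacy_arithmetic(self):
        # equal l, h difference 0.01 mol/kcal, E_p difference 1 kcal/mol
        pi = exchange_probability_legacy(0.0, 0.0, 1.0, 0.0, 0.0, 0.01, 0.0, 0.0)
        assert pi == pytest.approx(np.exp(-0.01))

    @given(finite, finite, finite, finite, finite, finite, finite, finite)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_legacy_detailed_balance(self, a, b, c, d, lm, hm, ln, hn):
        """The reverse move (same stages, replicas swapped) has exactly the
        reciprocal raw ratio."""
        fwd = legacy_log_ratio(a, b, c, d, lm, hm, ln, hn)
        rev = legacy_log_ratio(c, d, a, b, lm, hm, ln, hn)
        assert fwd + rev == pytest.approx(0.0, abs=1e-9)

    def test_generalized_identical_stages(self):
        m = StageSpec(0, 300.0, 0.5, 0.1)
        n = StageSpec(1, 300.0, 0.5, 0.1)
        assert exchange_probability_generalized(3.0, 1.0, -2.0, 0.3, m, n) == 1.0

    def test_generalized_balanced_equal_temperature(self):
        """Equal-T stages whose mu sit at their balanced values accept every
        swap regardless of the energies."""
        from sgsim.guiding import balanced_force_factor

        m = StageSpec(0, 300.0, 1.0, balanced_force_factor(1.0))
        n = StageSpec(1, 300.0, -0.5, balanced_force_factor(-0.5))
        pi = exchange_probability_generalized(7.0, 2.0, -1.0, -0.4, m, n)
        assert pi == 1.0

    @given(finite, finite, finite, finite,
           st.floats(0.1, 1.0), st.floats(-0.9, 0.9),
           st.floats(0.1, 1.0), st.floats(-0.9, 0.9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_generalized_detailed_balance(self, e1, d1, e2, d2, lm, mm, ln, mn):
        m = StageSpec(0, 280.0, lm, mm)
        n = StageSpec(1, 320.0, ln, mn)
        fwd = generalized_log_ratio(e1, d1, e2, d2, m, n)
        rev = generalized_log_ratio(e2, d2, e1, d1, m, n)
        assert fwd + rev == pytest.approx(0.0, abs=1e-9)


class _FakeLocal:
    def __init__(self, E_avg, E_avg2):
        self.E_avg, self.E_avg2 = E_avg, E_avg2


class _FakeState:
    def __init__(self, E_p, E_avg, E_avg2):
        self.E_p = E_p
        self.local = _FakeLocal(E_avg, E_avg2)


class _FakeSim:
    def __init__(self, E_p, E_avg=0.0, E_avg2=0.0):
        self.state = _FakeState(E_p, E_avg, E_avg2)
        self.guiding_sets = []

    def set_guiding(self, guiding, temperature=None):
        self.guiding_sets.append((guiding, temperature))


class TestAttemptExchange:
    def _pair(self, E_a=1.0, E_b=1.0):
        ra = ReplicaState(0, 0, _FakeSim(E_a))
        rb = ReplicaState(1, 1, _FakeSim(E_b))
        return ra, rb

    def test_certain_swap_accepted_and_counted(self):
        stages = [StageSpec(0, 300.0), StageSpec(1, 300.0)]
        ra, rb = self._pair()
        counters = {}
        ok = attempt_exchange(ra, rb, stages, GuidingParams(mode=Mode.LD, gamma=1.0),
                              np.random.default_rng(0), counters)
        assert ok and counters[(0, 1)] == [1, 1]
        assert (ra.current_stage, rb.current_stage) == (1, 0)

    def test_same_stage_pair_rejected_with_warning(self):
        stages = [StageSpec(0, 300.0), StageSpec(1, 300.0)]
        ra, rb = self._pair()
        rb.current_stage = 0
        with pytest.warns(RuntimeWarning):
            ok = attempt_exchange(ra, rb, stages,
                                  GuidingParams(mode=Mode.LD, gamma=1.0),
                                  np.random.default_rng(0), {})
        assert not ok

    def test_metropolis_fraction(self):
        """A pair with exchange probability 1/2 is accepted about half the
        time (binomial 3-sigma band over 10^4 attempts)."""
        dT = 300.0
        stages = [StageSpec(0, 300.0), StageSpec(1, 300.0 + dT)]
        # beta difference * energy difference = ln 2  ->  pi = 0.5
        dbeta = 1 / (KB * 300.0) - 1 / (KB * 600.0)
        dE = np.log(2.0) / dbeta
        rng = np.random.default_rng(77)
        acc = 0
        n = 10_000
        counters = {}
        for _ in range(n):
            ra = ReplicaState(0, 0, _FakeSim(-dE))
            rb = ReplicaState(1, 1, _FakeSim(0.0))
            acc += attempt_exchange(ra, rb, stages,
                                    GuidingParams(mode=Mode.LD, gamma=1.0),
                                    rng, counters)
        assert abs(acc / n - 0.5) < 3 * np.sqrt(0.25 / n)


@pytest.fixture(scope="module")
def sdw_rx():
    system, r0 = build_sdw_system()

    def run(stages, seed=1, n_cycles=40, exchange_interval=500, **kw):
        cfg = IntegratorConfig(
            dt=0.001, n_steps=0, temperature=300.0, seed=seed,
            record_every=100,
            guiding=GuidingParams(mode=Mode.SGLD, gamma=10.0),
        )
        return run_rxsgld(system, stages, cfg, r0, n_cycles=n_cycles,
                          exchange_interval=exchange_interval, **kw)

    return run


class TestLadders:
    def test_identical_stages_all_accepted_walk_covers_ladder(self, sdw_rx):
        stages = [StageSpec(i, 300.0) for i in range(4)]
        res = sdw_rx(stages, n_cycles=60)
        assert res.acceptance.attempts.sum() > 0
        assert (res.acceptance.ratio == 1.0).all()
        visited = set(res.stage_traces[res.stage_traces.replica == 0].stage)
        assert visited == {0, 1, 2, 3}

    def test_stage_assignments_stay_a_permutation(self, sdw_rx):
        stages = [StageSpec(i, 300.0, lam, 0.0)
                  for i, lam in enumerate((0.0, 0.5, 1.0))]
        res = sdw_rx(stages, n_cycles=30)
        trace = res.stage_traces
        for t, grp in trace.groupby("t"):
            assert sorted(grp.stage) == [0, 1, 2]

    def test_identical_ladder_preserves_sampling(self, sdw_rx, sdw_runner):
        """Exchanges between identical stages must not distort the sampled
        energy distribution (KS against a no-exchange run)."""
        stages = [StageSpec(0, 300.0), StageSpec(1, 300.0)]
        res = sdw_rx(stages, n_cycles=100, exchange_interval=1000, seed=3)
        e_rx = np.concatenate(
            [df.E_p.to_numpy() for df in res.frames_by_stage.values()]
        )
        plain, _ = sdw_runner(mode=Mode.SGLD, n_steps=100_000, seed=9,
                              record_every=100)
        e_plain = plain.frames.E_p.to_numpy()
        # subsample to ~independent frames (1 ps apart)
        ks = stats.ks_2samp(e_rx[::10], e_plain[::10])
        assert ks.pvalue > 0.01

    def test_legacy_and_generalized_agree_without_guiding(self, sdw_rx):
        stages = [StageSpec(i, 300.0) for i in range(3)]
        for mode in ("generalized", "legacy"):
            res = sdw_rx(stages, n_cycles=20, mode=mode)
            assert (res.acceptance.ratio == 1.0).all()

    def test_unequal_temperature_legacy_warns(self, sdw_rx):
        stages = [StageSpec(0, 300.0), StageSpec(1, 350.0)]
        with pytest.warns(RuntimeWarning, match="legacy"):
            sdw_rx(stages, n_cycles=2, mode="legacy")
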