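import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from nichesim import (
    AbsorbingStateError,
    LeapSettings,
    conserved_moieties,
    leap_mean,
    propensity_time_derivative,
    rre_derivative,
    rre_trajectory,
    sal_step,
    select_tau,
    simulate,
    simulate_ensemble,
    ssa_exact,
)
from nichesim.network import Reaction, ReactionNetwork, Species, SystemState
from nichesim.synthetic import (
    birth_death,
    birth_death_mean,
    dimerization,
    pure_death,
    two_state_switch,
)


def source_network(rate=5.0, x0=0):
    return ReactionNetwork(
        [Species("A", "cell", x0)],
        [Reaction("src", [], ["A"], rate, "transcription")],
    )


class TestLeapSettings:
    def test_defaults(self):
        s = LeapSettings()
        assert s.epsilon == 0.03
        assert s.ssa_threshold == 10

    @pytest.mark.parametrize(
        "kwargs", [{"epsilon": 0.0}, {"epsilon": 1.0}, {"ssa_threshold": -1},
                   {"max_tau": 0.0}]
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            LeapSettings(**kwargs)


class TestRREDerivative:
    def test_linear_decay(self):
        net = pure_death(rate=1.0, x0=1000)
        assert rre_derivative(net, net.initial_state()) == pytest.approx([-1000.0])

    def test_linear_birth(self):
        b = 1.7
        net = ReactionNetwork(
            [Species("A", "cell", 10)],
            [Reaction("birth", ["A"], ["A", "A"], b, "renewal")],
        )
        assert rre_derivative(net, np.array([10])) == pytest.approx([10 * b])

    def test_birth_death_by_hand(self):
        net = birth_death(b=2.0, d=1.0, x0=100)
        # 2*100 - 1*100 = +100
        assert rre_derivative(net, net.initial_state()) == pytest.approx([100.0])

    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    def test_conserved_moiety_has_zero_drift(self, a, b, ab):
        net = dimerization()
        x = np.array([a, b, ab])
        drift = rre_derivative(net, x)
        for w in conserved_moieties(net):
            assert w @ drift == pytest.approx(0.0, abs=1e-9)


class TestPropensityTimeDerivative:
    def test_zero_order_channel_is_static(self):
        net = source_network()
        assert propensity_time_derivative(net, np.array([3]), 0) == 0.0

    def test_linear_decay(self):
        net = pure_death(rate=1.0, x0=1000)
        # dr/dt = (dr/dx)(dx/dt) = 1 * (-1000)
        assert propensity_time_derivative(net, np.array([1000]), 0) == pytest.approx(
            -1000.0
        )

    def test_bimolecular_chain_rule(self):
        net = ReactionNetwork(
            [Species("A", "cell", 10), Species("B", "cell", 100),
             Species("AB", "complex", 0)],
            [Reaction("bind", ["A", "B"], ["AB"], 0.01, "binding")],
        )
        # dx/dt = (-10, -10, +10); dr/dt = 0.01*(100*(-10) + 10*(-10)) = -11
        assert propensity_time_derivative(net, np.array([10, 100, 0]), 0) == (
            pytest.approx(-11.0)
        )


class TestLeapMean:
    def test_reduces_to_r_tau_when_static(self):
        net = source_network(rate=5.0)
        assert leap_mean(net, np.array([0]), 0, 2.0) == pytest.approx(10.0)

    @given(st.floats(0.01, 5.0))
    def test_reduces_to_r_tau_property(self, tau):
        net = source_network(rate=5.0)
        assert leap_mean(net, np.array([0]), 0, tau) == pytest.approx(5.0 * tau)

    def test_quadratic_correction(self):
        # r=1000, dr/dt=-1000, tau=0.1: 100 - 1000*0.005 = 95
        net = pure_death(rate=1.0, x0=1000)
        assert leap_mean(net, np.array([1000]), 0, 0.1) == pytest.approx(95.0)

    def test_absent_reactant_gives_zero(self):
        net = pure_death(rate=1.0, x0=0)
        for tau in (0.1, 1.0, 10.0):
            assert leap_mean(net, np.array([0]), 0, tau) == 0.0

    def test_clamped_at_zero(self):
        # large tau: 1000*5 + 0.5*(-1000)*25 < 0 -> clamped
        net = pure_death(rate=1.0, x0=1000)
        assert leap_mean(net, np.array([1000]), 0, 5.0) == 0.0

    def test_nonpositive_tau_rejected(self):
        net = pure_death()
        with pytest.raises(ValueError):
            leap_mean(net, np.array([10]), 0, 0.0)


class TestSelectTau:
    def test_static_propensities_give_max_tau(self):
        net = source_network(rate=5.0)
        s = LeapSettings(max_tau=7.0)
        assert select_tau(net, np.array([0]), s) == pytest.approx(7.0)

    def test_criterion_by_hand(self):
        # death at rate 0.5, x=200: r=100, dr/dt = 0.5*(-100) = -50;
        # tau = eps*max(r, a)/|dr| = 0.03*100/50 = 0.06
        net = pure_death(rate=0.5, x0=200)
        s = LeapSettings(epsilon=0.03)
        assert select_tau(net, np.array([200]), s) == pytest.approx(0.06)

    def test_reversible_pair_at_equilibrium(self):
        net = two_state_switch(lambda_emt=0.1, lambda_met=0.1)
        s = LeapSettings(max_tau=10.0)
        # equal occupancy: the net RRE flow vanishes, so dr/dt = 0 for both
        assert select_tau(net, np.array([50, 50]), s) == pytest.approx(10.0)

    def test_absorbing_state_signalled(self):
        net = pure_death(rate=1.0, x0=0)
        with pytest.raises(AbsorbingStateError):
            select_tau(net, np.array([0]), LeapSettings())


class TestSalStep:
    def test_absorbing_state_advances_time_only(self):
        net = pure_death(rate=1.0, x0=0)
        s = LeapSettings(max_tau=4.0)
        out = sal_step(net, SystemState(1.0, np.array([0])), s, np.random.default_rng(0))
        assert out.time == pytest.approx(5.0)
        assert out.counts.tolist() == [0]

    def test_counts_stay_nonnegative(self):
        net = pure_death(rate=1.0, x0=5)
        rng = np.random.default_rng(1)
        state = SystemState(0.0, np.array([5]))
        for _ in range(50):
            state = sal_step(net, state, LeapSettings(), rng)
            assert (state.counts >= 0).all()

    def test_pure_death_ensemble_mean(self):
        # SAL-only ensemble of A -> 0 at rate 1, x0=1000; E X_1 = 1000/e
        net = pure_death(rate=1.0, x0=1000)
        s = LeapSettings(method="sal")
        summ = simulate_ensemble(net, 1.0, s, n=400, seed=7,
                                 grid=np.array([0.0, 1.0]))
        final = summ.counts_of("A")[:, -1]
        target = 1000.0 * np.exp(-1.0)
        se = final.std(ddof=1) / np.sqrt(len(final))
        assert abs(final.mean() - target) < 3 * se
        assert (summ.states >= 0).all()


class TestSsaExact:
    def test_pure_death_three_events(self):
        traj = ssa_exact(pure_death(rate=1.0, x0=3), 100.0, seed=0)
        a = traj.counts_of("A")
        assert a[0] == 3
        assert a[-1] == 0
        # exactly 3 decrements, each by one
        diffs = np.diff(a)
        assert (diffs[diffs != 0] == -1).all()
        assert (diffs != 0).sum() == 3

    def test_subcritical_birth_death_goes_extinct(self):
        # b=1 < d=2 from a single ancestor: extinction is certain
        net = birth_death(b=1.0, d=2.0, x0=1)
        extinct = 0
        for seed in range(200):
            traj = ssa_exact(net, 50.0, seed=seed)
            extinct += traj.counts_of("A")[-1] == 0
        assert extinct >= 190

    def test_times_strictly_increasing(self):
        traj = ssa_exact(birth_death(x0=20), 0.5, seed=3)
        assert (np.diff(traj.times) > 0).all()
        assert (traj.states >= 0).all()


class TestSimulate:
    def test_seeded_runs_are_bit_reproducible(self):
        net = birth_death(b=1.0, d=1.0, x0=50)
        t1 = simulate(net, 2.0, LeapSettings(), seed=11)
        t2 = simulate(net, 2.0, LeapSettings(), seed=11)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.states, t2.states)

    def test_two_state_occupancy_matches_detailed_balance(self):
        # 100 particles, lambda_emt=0.02, lambda_met=0.08: pi_MET = 0.8
        net = two_state_switch(lambda_emt=0.02, lambda_met=0.08, n=100)
        summ = simulate_ensemble(net, 400.0, LeapSettings(), n=60, seed=5)
        late = summ.times >= 200.0
        met_mean = summ.counts_of("MET")[:, late].mean()
        assert abs(met_mean - 80.0) < 4.0

    def test_critical_birth_death_mean_is_flat(self):
        net = birth_death(b=1.0, d=1.0, x0=100)
        summ = simulate_ensemble(net, 2.0, LeapSettings(), n=300, seed=9,
                                 grid=np.array([0.0, 1.0, 2.0]))
        final = summ.counts_of("A")[:, -1]
        se = final.std(ddof=1) / np.sqrt(len(final))
        assert abs(final.mean() - 100.0) < 3 * se


class TestSimulateEnsemble:
    def test_shapes_and_grid(self):
        net = birth_death(x0=30)
        grid = np.linspace(0.0, 1.0, 11)
        summ = simulate_ensemble(net, 1.0, LeapSettings(), n=8, seed=2, grid=grid)
        assert summ.states.shape == (8, 11, 1)
        assert np.array_equal(summ.times, grid)
        assert summ.n == 8

    def test_mean_within_replicate_envelope(self):
        net = birth_death(x0=30)
        summ = simulate_ensemble(net, 1.0, LeapSettings(), n=20, seed=4)
        m = summ.mean()
        assert (m >= summ.states.min(axis=0) - 1e-12).all()
        assert (m <= summ.states.max(axis=0) + 1e-12).all()

    def test_reproducible_for_seed(self):
        net = dimerization()
        a = simulate_ensemble(net, 1.0, LeapSettings(), n=10, seed=13)
        b = simulate_ensemble(net, 1.0, LeapSettings(), n=10, seed=13)
        assert np.array_equal(a.states, b.states)

    def test_growth_matches_analytic_mean(self):
        net = birth_death(b=2.0, d=1.0, x0=100)
        summ = simulate_ensemble(net, 2.0, LeapSettings(), n=300, seed=21,
                                 grid=np.array([0.0, 1.0, 2.0]))
        final = summ.counts_of("A")[:, -1]
        target = birth_death_mean(2.0, 1.0, 100, 2.0)
        se = final.std(ddof=1) / np.sqrt(len(final))
        assert abs(final.mean() - target) < 3 * se

    def test_input_validation(self):
        net = birth_death()
        with pytest.raises(ValueError):
            simulate_ensemble(net, 1.0, n=0)
        with pytest.raises(ValueError):
            simulate_ensemble(net, 0.0, n=2)

    def test_summary_round_trip(self, tmp_path):
        net = two_state_switch(n=5)
        summ = simulate_ensemble(net, 1.0, LeapSettings(), n=3, seed=0,
                                 grid=np.array([0.0, 0.5, 1.0]))
        summ.save(tmp_path / "t.csv", tmp_path / "t.json")
        import json

        import pandas as pd

        frame = pd.read_csv(tmp_path / "t.csv")
        assert set(frame.columns) == {"replicate", "time", "species", "count"}
        assert len(frame) == 3 * 3 * 2
        payload = json.loads((tmp_path / "t.json").read_text())
        assert payload["n"] == 3
        assert set(payload["species"]) == {"MET", "EMT"}


class TestEpsilonConvergence:
    def test_small_epsilon_end_state_matches_ssa(self):
        # as epsilon -> 0 the leaped end-state distribution converges to
        # the exact one; KS test on the two-state fixture, alpha = 0.01.
        # The horizon sits inside the relaxation transient, where the
        # propensity drift is nonzero and epsilon actually bounds the leap.
        net = two_state_switch(lambda_emt=0.02, lambda_met=0.08, n=50)
        grid = np.array([0.0, 5.0])
        exact = simulate_ensemble(net, 5.0, LeapSettings(method="ssa"),
                                  n=300, seed=100, grid=grid)
        leaped = simulate_ensemble(
            net, 5.0, LeapSettings(method="sal", epsilon=0.005),
            n=300, seed=200, grid=grid,
        )
        res = stats.ks_2samp(exact.counts_of("MET")[:, -1],
                             leaped.counts_of("MET")[:, -1])
        assert res.pvalue > 0.01
        assert (leaped.states >= 0).all()


class TestRRETrajectory:
    def test_linear_decay_closed_form(self):
        net = pure_death(rate=1.0, x0=1000)
        t, y = rre_trajectory(net, 3.0)
        assert np.allclose(y[:, 0], 1000.0 * np.exp(-t), rtol=1e-5)

    def test_dimerization_conserves_moieties(self):
        net = dimerization()
        t, y = rre_trajectory(net, 5.0)
        total_a = y[:, 0] + y[:, 2]
        assert np.allclose(total_a, total_a[0], rtol=1e-6)
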