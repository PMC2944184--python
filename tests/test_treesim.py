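import numpy as np
import pytest
from scipy.stats import kstest

from divtempo.chronogram import BranchingTimes
from divtempo.gamma import gamma_from_intervals, gamma_statistic
from divtempo.treesim import (
    SimulationConfig,
    pruned_yule_branching_times,
    sample_incomplete,
    simulate_birth_death,
    simulate_mk1_states,
    simulate_yule,
    two_rate_branching_times,
    yule_gamma_sample,
    yule_intervals,
)


class TestYule:
    def test_two_tip_mean_root_age(self):
        """E[root age] of a 2-tip tree is E[g_2] = 1/(2 lambda)."""
        rng = np.random.default_rng(5)
        ages = yule_intervals(2, 1.0, rng, size=10_000).ravel()
        assert ages.mean() == pytest.approx(0.5, abs=0.02)

    def test_outputs_are_valid_chronograms(self):
        for seed in range(5):
            t = simulate_yule(25, 1.0, seed)
            assert t.n_tips == 25
            bt = t.branching_times()
            assert len(bt.times) == 24
            assert np.all(bt.intervals >= 0)

    def test_seed_determinism(self):
        a = simulate_yule(40, 1.0, 123).to_newick()
        b = simulate_yule(40, 1.0, 123).to_newick()
        assert a == b

    def test_min_tips_enforced(self):
        with pytest.raises(ValueError):
            simulate_yule(1, 1.0, 0)

    def test_rate_only_rescales_time(self):
        """gamma of the null cannot depend on the simulation rate."""
        g1 = yule_gamma_sample(40, 40, 500, np.random.default_rng(1), birth_rate=0.1)
        g2 = yule_gamma_sample(40, 40, 500, np.random.default_rng(2), birth_rate=10.0)
        assert kstest(g1, g2).pvalue > 0.01


class TestIncompleteSampling:
    def test_identity_when_keeping_all(self):
        t = simulate_yule(15, 1.0, 2)
        assert sample_incomplete(t, 15, 0) is t

    def test_keep_two(self):
        t = simulate_yule(15, 1.0, 2)
        p = sample_incomplete(t, 2, 0)
        assert len(p.branching_times().times) == 1

    def test_fast_path_matches_tree_route(self):
        """Array pruning and dendropy pruning give identical branching
        times when fed the same draws."""
        for seed in range(10):
            rng1 = np.random.default_rng(seed)
            times_fast = pruned_yule_branching_times(12, 6, rng1)
            # replay: same generator consumption order as the fast path
            rng2 = np.random.default_rng(seed)
            t = simulate_yule(12, 1.0, rng2)
            chosen = rng2.choice(12, size=6, replace=False)
            # tip index i carries label t<i+1> by construction
            p = t.prune({f"t{i + 1:02d}" for i in chosen})
            np.testing.assert_allclose(
                p.branching_times().times, times_fast, atol=1e-9
            )

    def test_pruning_pushes_gamma_negative(self):
        rng = np.random.default_rng(7)
        g_pruned = yule_gamma_sample(122, 90, 800, rng)
        g_complete = yule_gamma_sample(90, 90, 800, rng)
        assert g_pruned.mean() < g_complete.mean() - 0.3

    def test_bounds(self):
        t = simulate_yule(10, 1.0, 0)
        with pytest.raises(ValueError):
            sample_incomplete(t, 1, 0)
        with pytest.raises(ValueError):
            sample_incomplete(t, 11, 0)


class TestBirthDeath:
    def test_mu_zero_reduces_to_yule(self):
        a = simulate_birth_death(20, 1.0, 0.0, seed=9).to_newick()
        b = simulate_yule(20, 1.0, seed=9).to_newick()
        assert a == b

    def test_survivor_tree_is_ultrametric(self):
        for seed in range(5):
            t = simulate_birth_death(15, 1.0, 0.5, seed=seed)
            assert t.n_tips == 15  # Chronogram validation enforces ultrametricity

    def test_extinction_pulls_gamma_up(self):
        """High relative extinction concentrates reconstructed nodes near
        the present, raising mean gamma above the pure-birth value."""
        n, reps = 25, 250
        g_bd = np.empty(reps)
        g_pb = np.empty(reps)
        rng = np.random.default_rng(3)
        for i in range(reps):
            g_bd[i] = gamma_statistic(
                simulate_birth_death(n, 1.0, 0.9, seed=rng).branching_times()
            ).gamma
            g_pb[i] = gamma_statistic(
                simulate_yule(n, 1.0, seed=rng).branching_times()
            ).gamma
        assert g_bd.mean() > g_pb.mean() + 0.3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_birth_death(10, 1.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_birth_death(10, 1.0, -0.1, seed=0)


class TestMk1States:
    def test_zero_rate_copies_root(self):
        t = simulate_yule(50, 1.0, 4)
        st = simulate_mk1_states(t, 0.0, 1, seed=0)
        assert set(st.values()) == {1}

    def test_stationary_limit(self):
        t = simulate_yule(1000, 1.0, 4)
        st = simulate_mk1_states(t, 50.0, 0, seed=1)
        frac = np.mean([v for v in st.values()])
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_slow_rate_mostly_retains_root_state(self):
        """At q ~ 0.007 on a root-age-16 tree most tips keep the root
        area, matching a generally low transition rate."""
        t = simulate_yule(200, 1.0, 8)
        t = t.rescale(16.0 / t.root_age)
        st = simulate_mk1_states(t, 0.007, 1, seed=2)
        assert np.mean([v for v in st.values()]) > 0.7

    def test_negative_rate_rejected(self):
        t = simulate_yule(5, 1.0, 0)
        with pytest.raises(ValueError):
            simulate_mk1_states(t, -0.1, 1, seed=0)


class TestTwoRate:
    def test_interval_rates(self):
        rng = np.random.default_rng(0)
        bt = two_rate_branching_times(200, 5.0, 1.0, 100, rng)
        assert bt.n == 200
        assert len(bt.times) == 199
        # early intervals (many small gaps) should be much shorter on average
        g = bt.intervals
        k = np.arange(2, 201)
        early = (g[k <= 100] * k[k <= 100]).mean()
        late = (g[k > 100] * k[k > 100]).mean()
        assert late / early > 2.0


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_tips=1)
        with pytest.raises(ValueError):
            SimulationConfig(n_tips=5, birth_rate=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_tips=5, birth_rate=1.0, death_rate=1.5)
        cfg = SimulationConfig(n_tips=5, death_rate=0.3)
        assert cfg.reps == 1
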