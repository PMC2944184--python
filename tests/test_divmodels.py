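import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from divtempo import parse_newick
from divtempo.chronogram import BranchingTimes
from divtempo.divmodels import (
    MODEL_NAMES,
    bd_loglik,
    calibrate_delta_critical,
    compare_models,
    delta_aic_rc,
    fit_all,
    fit_model,
)
from divtempo.treesim import simulate_yule, two_rate_branching_times

# 40-tip reconstructed birth-death chronogram simulated at lambda=1, mu=0.6
# (seed 11); reference values computed independently with ape::birthdeath,
# which maximizes the same root-conditioned likelihood.
BD40_APE_LNL = 58.22234
BD40_APE_A = 0.7913662434  # d/b
BD40_APE_R = 0.2782548966  # b-d


def pb_lnL(bt, lam):
    """Direct arithmetic evaluation of the pure-birth log-likelihood."""
    k = np.arange(2, bt.n + 1)
    T = float(np.sum(k * bt.intervals))
    return float(gammaln(bt.n)) + (bt.n - 2) * math.log(lam) - lam * T


class TestPureBirth:
    def test_closed_form_on_forced_example(self):
        bt = BranchingTimes(n=3, times=np.array([2.0, 1.0]))
        fit = fit_model("pure_birth", bt)
        assert fit.params["lambda"] == pytest.approx(0.2, abs=1e-12)

    def test_closed_form_matches_numeric_optimizer(self):
        for seed in range(20):
            bt = simulate_yule(30, 0.5, seed).branching_times()
            fit = fit_model("pure_birth", bt)
            res = minimize_scalar(
                lambda lam: -pb_lnL(bt, lam), bounds=(1e-6, 100), method="bounded",
                options={"xatol": 1e-12},
            )
            assert fit.params["lambda"] == pytest.approx(res.x, abs=1e-6)
            assert fit.lnL == pytest.approx(-res.fun, abs=1e-9)

    def test_aic_bookkeeping(self):
        bt = simulate_yule(30, 1.0, 0).branching_times()
        fit = fit_model("pure_birth", bt)
        assert fit.AIC == pytest.approx(2 * fit.k_params - 2 * fit.lnL)


class TestBirthDeath:
    def test_matches_external_reference_fit(self, data_dir):
        t = parse_newick((data_dir / "trees" / "bd40.nwk").read_text())
        fit = fit_model("birth_death", t.branching_times())
        assert fit.lnL == pytest.approx(BD40_APE_LNL, abs=1e-4)
        assert fit.params["a"] == pytest.approx(BD40_APE_A, abs=1e-4)
        assert fit.params["r"] == pytest.approx(BD40_APE_R, abs=1e-4)

    def test_reduces_to_pure_birth_at_zero_extinction(self):
        bt = simulate_yule(40, 1.0, 3).branching_times()
        pb = fit_model("pure_birth", bt)
        assert bd_loglik(bt, pb.params["lambda"], 0.0) == pytest.approx(
            pb.lnL, abs=1e-10
        )

    def test_nests_pure_birth(self):
        for seed in range(10):
            bt = simulate_yule(35, 1.0, seed).branching_times()
            fits = fit_all(bt)
            assert fits["birth_death"].lnL >= fits["pure_birth"].lnL - 1e-6


class TestDensityDependent:
    def test_ddl_with_huge_K_recovers_pure_birth(self):
        bt = simulate_yule(50, 1.0, 9).branching_times()
        pb = fit_model("pure_birth", bt)
        n, g = bt.n, bt.intervals
        k = np.arange(2, n + 1)
        K = 1e8
        A = float(np.sum(g * k * (1 - k / K)))
        lam0 = (n - 2) / A
        lnL = (
            float(np.sum(np.log(np.arange(2, n) * (1 - np.arange(2, n) / K))))
            + (n - 2) * math.log(lam0)
            - (n - 2)
        )
        assert lnL == pytest.approx(pb.lnL, rel=1e-6)

    def test_ddx_at_zero_exponent_is_pure_birth(self):
        bt = simulate_yule(50, 1.0, 9).branching_times()
        fits = fit_all(bt)
        assert fits["DDX"].lnL >= fits["pure_birth"].lnL - 1e-9

    def test_ddl_feasibility(self):
        bt = simulate_yule(30, 1.0, 1).branching_times()
        fit = fit_model("DDL", bt)
        assert fit.params["K"] > bt.n
        assert fit.params["lambda0"] > 0


class TestYule2Rate:
    def test_equal_rates_reproduce_pure_birth(self):
        bt = simulate_yule(30, 1.0, 5).branching_times()
        pb = fit_model("pure_birth", bt)
        # the two-rate likelihood at lambda1 = lambda2 = lambda_hat equals
        # the one-rate likelihood for any shift placement
        assert pb_lnL(bt, pb.params["lambda"]) == pytest.approx(pb.lnL, abs=1e-9)
        y2 = fit_model("yule2rate", bt)
        assert y2.lnL >= pb.lnL - 1e-9
        assert y2.k_params == 3

    def test_shift_inside_tree(self):
        bt = simulate_yule(30, 1.0, 5).branching_times()
        y2 = fit_model("yule2rate", bt)
        assert 0 < y2.params["t_shift"] < bt.root_age

    def test_recovers_strong_shift(self):
        bt = two_rate_branching_times(200, 5.0, 1.0, 100, np.random.default_rng(2))
        y2 = fit_model("yule2rate", bt)
        assert y2.params["lambda1"] == pytest.approx(5.0, rel=0.35)
        assert y2.params["lambda2"] == pytest.approx(1.0, rel=0.35)


class TestComparison:
    def test_extra_parameters_penalized_under_null(self):
        # when every rate-variable fit collapses onto the pure-birth
        # likelihood, AIC must prefer the rate-constant model
        bt = simulate_yule(60, 1.0, 14).branching_times()
        fits = fit_all(bt)
        if fits["yule2rate"].lnL - fits["pure_birth"].lnL < 1.0:
            assert delta_aic_rc(fits) < 4.0
        comp = compare_models(fits, critical_delta=8.0)
        assert comp.selected in ("pure_birth", "birth_death")

    def test_boundary_retains_rate_constant(self):
        bt = simulate_yule(40, 1.0, 6).branching_times()
        fits = fit_all(bt)
        delta = delta_aic_rc(fits)
        comp = compare_models(fits, critical_delta=delta)  # equality: keep RC
        assert comp.selected == comp.best_rate_constant

    def test_missing_fit_reported(self):
        bt = simulate_yule(20, 1.0, 0).branching_times()
        fits = fit_all(bt)
        del fits["DDL"]
        with pytest.raises(ValueError, match="DDL"):
            compare_models(fits, 0.0)

    def test_strong_two_rate_signal_selected(self):
        rng = np.random.default_rng(17)
        crit = calibrate_delta_critical(200, 150, alpha=0.05, seed=rng)
        wins = 0
        for _ in range(30):
            bt = two_rate_branching_times(200, 5.0, 1.0, 100, rng)
            comp = compare_models(fit_all(bt), crit)
            wins += comp.selected == "yule2rate"
        assert wins > 15


class TestCalibration:
    def test_threshold_construction(self):
        crit, deltas = calibrate_delta_critical(
            40, 300, alpha=0.05, seed=0, return_null=True
        )
        frac = np.mean(deltas > crit)
        assert frac <= 0.05 + 1 / 300
        assert crit >= np.quantile(deltas, 0.90)

    def test_alpha_one_gives_min(self):
        crit, deltas = calibrate_delta_critical(
            20, 150, alpha=1.0, seed=1, return_null=True
        )
        assert crit == deltas.min()

    def test_stable_across_seeds(self):
        crits = [
            calibrate_delta_critical(40, 300, alpha=0.05, seed=s) for s in range(4)
        ]
        assert np.std(crits) < 0.8


class TestRecovery:
    def test_yule_rate_recovery(self):
        """Mean lambda-hat over simulated pure-birth trees is unbiased."""
        rng = np.random.default_rng(31)
        lam_hats = []
        for _ in range(300):
            bt = simulate_yule(100, 0.2, rng).branching_times()
            lam_hats.append(fit_model("pure_birth", bt).params["lambda"])
        assert np.mean(lam_hats) == pytest.approx(0.2, rel=0.05)

    def test_unknown_model_rejected(self):
        bt = simulate_yule(10, 1.0, 0).branching_times()
        with pytest.raises(ValueError):
            fit_model("yule3000", bt)

    def test_aicc_option(self):
        bt = simulate_yule(30, 1.0, 0).branching_times()
        plain = fit_model("DDX", bt)
        corr = fit_model("DDX", bt, use_aicc=True)
        assert corr.AIC > plain.AIC
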