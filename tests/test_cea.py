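"""SUR estimation, bootstrap, ICER/dominance and CEAC laws."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_adjusted_dataset, stack_of
from rdcea.cea import (
    SureSpec,
    design_matrix,
    bootstrap_cea,
    ceac,
    fit_sure,
    icer_and_dominance,
    quadrant_shares,
    run_base_case,
)


def _ols(X, y):
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    return b


class TestSure:
    def test_equals_per_equation_ols_with_identical_regressors(self):
        # textbook SUR property, checked against a hand-rolled OLS oracle
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(30, 80)
            df = make_adjusted_dataset(int(n), 50.0, 0.01,
                                       seed=int(rng.integers(1 << 30)))
            fit = fit_sure(df)
            X, names = design_matrix(df, SureSpec())
            i = names.index("treated")
            assert fit.delta_cost == pytest.approx(
                _ols(X, df.total_cost_6m.to_numpy())[i], abs=1e-8)
            assert fit.delta_qaly == pytest.approx(
                _ols(X, df.qaly.to_numpy())[i], abs=1e-8)

    @pytest.mark.parametrize("truth", [(50.0, 0.01), (37.0, -0.006)])
    def test_parameter_recovery_within_three_se(self, truth):
        dc, dq = truth
        df = make_adjusted_dataset(5000, dc, dq, seed=42)
        fit = fit_sure(df)
        assert abs(fit.delta_cost - dc) < 3 * fit.se_delta_cost
        assert abs(fit.delta_qaly - dq) < 3 * fit.se_delta_qaly

    def test_single_arm_design_rejected(self):
        df = make_adjusted_dataset(100, 0, 0, seed=1)
        df["arm"] = "SoC"
        with pytest.raises(ValueError, match="arm"):
            fit_sure(df)

    def test_missing_cells_rejected(self):
        df = make_adjusted_dataset(50, 0, 0, seed=1)
        df.loc[0, "qaly"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            fit_sure(df)

    def test_rank_deficient_design_rejected(self):
        df = make_adjusted_dataset(100, 0, 0, seed=2)
        df["dup"] = df["utility_baseline"]
        spec = SureSpec(adjusters=["utility_baseline", "dup"])
        with pytest.raises(ValueError, match="rank"):
            fit_sure(df, spec)

    def test_residual_covariance_captures_correlation(self):
        rng = np.random.default_rng(3)
        n = 4000
        e = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], n)
        df = make_adjusted_dataset(n, 0, 0, seed=3)
        df["total_cost_6m"] = 100 + 50 * e[:, 0]
        df["qaly"] = 0.3 + 0.02 * e[:, 1]
        fit = fit_sure(df, SureSpec(adjusters=[]))
        rho = fit.resid_cov[0, 1] / np.sqrt(fit.resid_cov[0, 0]
                                            * fit.resid_cov[1, 1])
        assert rho == pytest.approx(0.8, abs=0.05)


class TestBootstrap:
    def test_identity_resample_reproduces_point_estimate(self):
        df = make_adjusted_dataset(300, 40.0, 0.005, seed=5)
        reps = bootstrap_cea(stack_of(df), B=1, identity_resample=True)
        fit = fit_sure(df)
        assert reps.delta_cost[0] == pytest.approx(fit.delta_cost, abs=1e-8)
        assert reps.delta_qaly[0] == pytest.approx(fit.delta_qaly, abs=1e-8)

    def test_noiseless_data_gives_zero_variance_replicates(self):
        df = make_adjusted_dataset(400, 80.0, 0.02, seed=6,
                                   cost_sd=0.0, qaly_sd=0.0)
        reps = bootstrap_cea(stack_of(df), B=25, seed=1)
        assert np.allclose(reps.delta_cost, 80.0, atol=1e-6)
        assert np.allclose(reps.delta_qaly, 0.02, atol=1e-9)

    def test_seed_determinism_and_stratification(self):
        df = make_adjusted_dataset(300, 40.0, 0.005, seed=7)
        a = bootstrap_cea(stack_of(df), B=20, seed=9)
        b = bootstrap_cea(stack_of(df), B=20, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(bootstrap_cea(stack_of(df), B=20, seed=10))


class TestIcer:
    @pytest.mark.parametrize("dc,de,icer,label", [
        (37.0, -0.006, np.nan, "dominated"),
        (100.0, 0.01, 10_000.0, "tradeoff_NE"),
        (-50.0, 0.02, np.nan, "dominant"),
        (-5.0, -0.001, 5_000.0, "tradeoff_SW"),
        (10.0, 0.0, np.nan, "undefined_ratio_cost_positive"),
        (0.0, 0.0, np.nan, "undefined_ratio_cost_zero"),
    ])
    def test_quadrants(self, dc, de, icer, label):
        out = icer_and_dominance(dc, de)
        assert out.label == label
        if np.isnan(icer):
            assert np.isnan(out.icer)
        else:
            assert out.icer == pytest.approx(icer)


HAND_REPLICATES = pd.DataFrame({
    "replicate": [1, 2, 3],
    "delta_cost": [10.0, -5.0, 20.0],
    "delta_qaly": [0.001, 0.002, -0.001],
})


class TestCeac:
    def test_hand_enumerated_example(self):
        curve = ceac(HAND_REPLICATES, np.array([0.0, 20_000.0]))
        # NMB at 20k: {10, 45, -40} -> 2/3; at lambda=0: fraction dc<0 -> 1/3
        assert curve.at(20_000) == pytest.approx(2 / 3)
        assert curve.at(0) == pytest.approx(1 / 3)

    def test_limits(self):
        lam = np.array([0.0, 1e9])
        curve = ceac(HAND_REPLICATES, lam)
        assert curve.probability[-1] == pytest.approx(
            (HAND_REPLICATES.delta_qaly > 0).mean())

    def test_all_dominant_gives_probability_one_everywhere(self):
        reps = pd.DataFrame({"replicate": [1, 2], "delta_cost": [-1.0, -2.0],
                             "delta_qaly": [0.01, 0.02]})
        curve = ceac(reps, np.arange(0, 50_001, 1000))
        assert (curve.probability == 1.0).all()

    def test_monotone_when_all_gains_positive(self):
        rng = np.random.default_rng(11)
        reps = pd.DataFrame({"replicate": np.arange(200),
                             "delta_cost": rng.normal(50, 30, 200),
                             "delta_qaly": np.abs(rng.normal(0.01, 0.005, 200))})
        curve = ceac(reps, np.arange(0, 50_001, 1000))
        assert (np.diff(curve.probability) >= 0).all()

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            ceac(HAND_REPLICATES.iloc[:0])


class TestRunBaseCase:
    def test_composition_identity_on_deterministic_fixture(self):
        df = make_adjusted_dataset(300, 40.0, 0.005, seed=12)
        res = run_base_case(stack_of(df), B=1, identity_resample=True, seed=0)
        fit = fit_sure(df)
        assert res.delta_cost == pytest.approx(fit.delta_cost, abs=1e-10)
        assert res.delta_qaly == pytest.approx(fit.delta_qaly, abs=1e-10)

    def test_point_estimate_is_mean_over_imputations(self):
        dfs = [make_adjusted_dataset(200, 40.0, 0.005, seed=s)
               for s in (1, 2, 3)]
        # align arms/covariates; vary only outcomes across 'imputations'
        res = run_base_case(stack_of(*dfs), B=2, seed=0)
        expected = np.mean([fit_sure(d).delta_cost for d in dfs])
        assert res.delta_cost == pytest.approx(expected, abs=1e-10)

    def test_strong_effect_is_dominant_with_ceac_one(self):
        df = make_adjusted_dataset(3000, -100.0, 0.05, seed=13)
        res = run_base_case(stack_of(df), B=100, seed=4)
        assert res.icer.label == "dominant"
        assert res.ceac.probability.min() > 0.99

    def test_quadrant_shares_sum_to_one(self):
        df = make_adjusted_dataset(500, 10.0, 0.0005, seed=14)
        res = run_base_case(stack_of(df), B=200, seed=5)
        assert sum(quadrant_shares(res.replicates).values()) == pytest.approx(1.0)
        lo, hi = res.ci_cost
        assert lo <= hi
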