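"""Missingness diagnostics, simple fills, MICE-PMM, MNAR scenarios."""

import numpy as np
import pandas as pd
import pytest

import rdcea
from rdcea.imputation import (
    CompletedDatasetStack,
    ImputationConfig,
    MnarScenario,
    apply_mnar_scenario,
    build_scenario_grid,
    check_m_rule_of_thumb,
    impute_baseline_simple,
    mice_pmm,
    missingness_diagnostics,
)


class TestDiagnostics:
    def test_recovers_female_missingness_odds(self):
        rng = np.random.default_rng(0)
        n = 8000
        female = rng.random(n) < 0.5
        p = 1 / (1 + np.exp(-(-1.0 + 1.0 * female)))
        df = pd.DataFrame({
            "sex": np.where(female, "female", "male"),
            "age_years": 65 + rng.gamma(2, 4, n),
            "utility_baseline": rng.normal(0.8, 0.1, n),
            "utility_6m": np.where(rng.random(n) < p, np.nan,
                                   rng.normal(0.8, 0.1, n)),
        })
        out = missingness_diagnostics(df, "qaly_missing",
                                      covariates=["sex", "age_years"])
        coef = out.loc["sex[male]", "coef"]
        se = out.loc["sex[male]", "se"]
        assert abs(coef - (-1.0)) < 3 * se  # male is the non-reference level
        assert out.loc["sex[male]", "odds_ratio"] == pytest.approx(np.exp(coef))

    def test_no_missingness_is_an_error(self):
        df = pd.DataFrame({"sex": ["f", "m"], "utility_baseline": [0.5, 0.6],
                           "utility_6m": [0.5, 0.6]})
        with pytest.raises(ValueError, match="no missingness"):
            missingness_diagnostics(df, "qaly_missing", covariates=["sex"])

    def test_perfect_separation_is_reported(self):
        df = pd.DataFrame({
            "x": np.r_[np.zeros(20), np.ones(20)].astype(float),
            "utility_baseline": 0.8,
            "utility_6m": np.r_[np.full(20, 0.8), np.full(20, np.nan)],
        })
        with pytest.raises(RuntimeError, match="separation"):
            missingness_diagnostics(df, "qaly_missing", covariates=["x"])


class TestSimpleImputation:
    def test_mean_mode_and_tie_rules(self):
        df = pd.DataFrame({
            "age_years": [70.0, 80.0, np.nan],
            "sex": ["M", "M", np.nan],
            "education": ["a", "b", np.nan],  # tie -> lowest in sort order
        })
        out = impute_baseline_simple(df, continuous=["age_years"],
                                     categorical=["sex", "education"])
        assert out.age_years.iloc[2] == 75.0
        assert out.sex.iloc[2] == "M"
        assert out.education.iloc[2] == "a"

    def test_identity_when_complete(self):
        df = pd.DataFrame({"age_years": [70.0, 80.0], "sex": ["M", "F"]})
        pd.testing.assert_frame_equal(impute_baseline_simple(df), df)

    def test_all_missing_column_raises(self):
        df = pd.DataFrame({"age_years": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="age_years"):
            impute_baseline_simple(df, continuous=["age_years"], categorical=[])


def _toy_frame(y):
    n = len(y)
    return pd.DataFrame({
        "arm": ["SoC"] * n,
        "x": np.linspace(0, 1, n),
        "y": y,
    })


class TestMicePmm:
    def test_no_missing_cells_gives_identical_copies(self, small_analysis):
        complete = small_analysis.dropna().reset_index(drop=True)
        stack = rdcea.impute_cohort(complete, ImputationConfig(m_imputations=3,
                                                               seed=0))
        assert stack.m == 3
        for ds in stack.datasets:
            pd.testing.assert_frame_equal(ds, stack.datasets[0])

    def test_imputed_value_among_knn_donors_by_exhaustive_ranking(self):
        # one missing cell, 6 donors, knn=5: the fill must come from the 5
        # donors nearest in predicted mean, verified by brute force
        rng = np.random.default_rng(4)
        y = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0, np.nan]
        df = _toy_frame(y)
        cfg = ImputationConfig(m_imputations=5, knn=5, seed=4,
                               predictors=["x"], max_iterations=3)
        stack = mice_pmm(df, ["y"], cfg)
        # oracle: OLS of y on [1, x] over observed rows
        obs = df.y.notna()
        X = np.column_stack([np.ones(len(df)), df.x])
        beta, *_ = np.linalg.lstsq(X[obs], df.y[obs], rcond=None)
        pred = X @ beta
        d = np.abs(pred[obs.to_numpy()] - pred[-1])
        top5 = set(np.array(y)[:-1][np.argsort(d)[:5]])
        for ds in stack.datasets:
            assert ds.y.iloc[-1] in top5

    def test_observed_preserved_range_respected_and_deterministic(self, small_analysis, small_stack):
        stack = small_stack
        targets = list(stack.mask.columns)
        for ds in stack.datasets:
            # observed cells exactly equal the input
            for t in targets:
                obs = ~stack.mask[t]
                pd.testing.assert_series_equal(ds.loc[obs, t],
                                               small_analysis.loc[obs, t])
            # PMM range property, per column and arm
            for t in targets:
                for arm in ["SoC", "SG"]:
                    rows = small_analysis.arm == arm
                    observed = small_analysis.loc[rows, t].dropna()
                    imputed = ds.loc[rows & stack.mask[t], t]
                    if len(imputed) and len(observed):
                        assert imputed.min() >= observed.min()
                        assert imputed.max() <= observed.max()
        # between-imputation variability: not every dataset identical
        cell_values = np.array([
            ds.loc[stack.mask["utility_6m"], "utility_6m"].to_numpy()
            for ds in stack.datasets
        ])
        assert (cell_values.std(axis=0) > 0).any()
        # seed determinism
        again = rdcea.impute_cohort(
            small_analysis, ImputationConfig(m_imputations=4, seed=11))
        for a, b in zip(stack.datasets, again.datasets):
            pd.testing.assert_frame_equal(a, b)

    def test_insufficient_donors_raise(self):
        df = _toy_frame([1.0, np.nan, np.nan, np.nan, np.nan, np.nan, 2.0])
        cfg = ImputationConfig(m_imputations=2, knn=5, predictors=["x"])
        with pytest.raises(ValueError, match="donors"):
            mice_pmm(df, ["y"], cfg)

    def test_mar_bias_corrected_toward_full_data_mean(self):
        # y depends on x; missingness depends on x (MAR): the complete-case
        # mean is biased, the pooled imputed mean is not
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.normal(0, 1, n)
        y_full = 2.0 + 1.5 * x + rng.normal(0, 0.5, n)
        miss = rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 1.5 * x)))
        df = pd.DataFrame({"arm": "SoC", "x": x,
                           "y": np.where(miss, np.nan, y_full)})
        cfg = ImputationConfig(m_imputations=10, knn=5, seed=7,
                               predictors=["x"], max_iterations=5)
        stack = mice_pmm(df, ["y"], cfg)
        pooled_mean = np.mean([ds.y.mean() for ds in stack.datasets])
        cc_bias = abs(df.y.mean() - y_full.mean())
        mi_bias = abs(pooled_mean - y_full.mean())
        assert cc_bias > 0.3          # the MAR mechanism really biases CC
        assert mi_bias < cc_bias / 3  # MI removes most of it

    def test_m_rule_of_thumb_helper(self):
        df = pd.DataFrame({"y": [1.0, np.nan, 3.0, np.nan]})  # 50% missing
        assert check_m_rule_of_thumb(df, ["y"], 50)
        assert not check_m_rule_of_thumb(df, ["y"], 40)


class TestMnar:
    def test_grid_is_the_seven_standard_scenarios(self):
        grid = build_scenario_grid()
        assert [s.name for s in grid] == list("abcdefg")
        c = grid[2]
        assert c.utility_scale == {"SoC": 0.9, "SG": 0.9}
        assert c.cost_scale == {"SoC": 1.1, "SG": 1.1}
        d = grid[3]
        assert d.utility_scale == {"SoC": 1.0, "SG": 0.9}

    def test_scenario_a_scales_imputed_utilities_only(self, small_analysis,
                                                      small_stack):
        scen = build_scenario_grid()[0]
        out = apply_mnar_scenario(small_stack, scen)
        for ds0, ds1 in zip(small_stack.datasets, out.datasets):
            imp = small_stack.mask["utility_6m"]
            assert np.allclose(ds1.loc[imp, "utility_6m"],
                               0.9 * ds0.loc[imp, "utility_6m"])
            obs = ~imp
            pd.testing.assert_series_equal(ds1.loc[obs, "utility_6m"],
                                           ds0.loc[obs, "utility_6m"])
            # cost cells untouched under scenario (a)
            pd.testing.assert_series_equal(ds1["cost_hospital_6m"],
                                           ds0["cost_hospital_6m"])

    def test_single_arm_cost_scenario(self, small_stack):
        scen = build_scenario_grid()[5]  # (f): cost up in the treated arm only
        out = apply_mnar_scenario(small_stack, scen)
        ds0, ds1 = small_stack.datasets[0], out.datasets[0]
        imp = small_stack.mask["cost_hospital_6m"]
        sg = ds0.arm == "SG"
        assert np.allclose(ds1.loc[imp & sg, "cost_hospital_6m"],
                           1.1 * ds0.loc[imp & sg, "cost_hospital_6m"])
        pd.testing.assert_series_equal(ds1.loc[~sg, "cost_hospital_6m"],
                                       ds0.loc[~sg, "cost_hospital_6m"])

    def test_identity_scenario_is_a_no_op(self, small_stack):
        ident = MnarScenario("id", {"SoC": 1.0, "SG": 1.0},
                             {"SoC": 1.0, "SG": 1.0})
        out = apply_mnar_scenario(small_stack, ident)
        for a, b in zip(small_stack.datasets, out.datasets):
            pd.testing.assert_frame_equal(a, b)

    def test_unknown_arm_rejected(self, small_stack):
        bad = MnarScenario("x", {"Placebo": 0.9}, {})
        with pytest.raises(ValueError, match="unknown arm"):
            apply_mnar_scenario(small_stack, bad)
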