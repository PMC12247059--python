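"""Missing-data handling: diagnostics, simple baseline fills, MICE-PMM,
and pattern-mixture MNAR scenarios.

The workflow mirrors standard practice for within-study economic
evaluations: (i) diagnose missingness with logistic regressions of
missing-indicators on baseline covariates; (ii) complete baseline covariates
by mean (continuous) / mode (categorical) imputation so they can serve as
predictors; (iii) impute costs (at the aggregated cost-group level) and
utilities by treatment arm with multiple imputation by chained equations,
using predictive mean matching (PMM) so every imputed value is an observed
donor value — robust to the skewness of cost data; (iv) probe the
missing-at-random assumption by pattern-mixture scenarios that scale the
*imputed* cells only (utility x0.9 and/or cost x1.1, per arm).

PMM details: for each incomplete variable, a linear regression on the
predictors (plus the other incomplete variables at their current fill) is
fitted to the observed rows; each missing cell receives the observed value
of one of the ``knn`` donors closest in predicted mean, chosen uniformly at
random, with ties in distance broken toward the lowest row position before
the uniform draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_cohort import UTILITY_CEIL, UTILITY_FLOOR

logger = logging.getLogger("rdcea")

DEFAULT_PREDICTORS = [
    "age_years", "sex", "ethnicity", "living_alone", "education",
    "gds_baseline", "comorbidity_count", "utility_baseline",
]

DEFAULT_DIAGNOSTIC_COVARIATES = [
    "age_years", "sex", "ethnicity", "living_alone", "education",
    "gds_baseline", "comorbidity_count",
]


def _design(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design matrix: passthrough numerics, reference-coded dummies.

    Reference levels are fixed alphabetically (first sorted level dropped)
    so designs are deterministic across runs and resamples.
    """
    parts = []
    for c in columns:
        col = df[c]
        if col.dtype == bool:
            parts.append(col.astype(float).rename(c))
        elif pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                parts.append((col == lev).astype(float).rename(f"{c}[{lev}]"))
    out = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
    out.insert(0, "const", 1.0)
    return out


def missingness_diagnostics(df: pd.DataFrame,
                            outcome: str = "total_cost_missing",
                            covariates: list[str] | None = None) -> pd.DataFrame:
    """Logistic regression of a missing-indicator on baseline covariates.

    ``outcome`` is ``"total_cost_missing"`` (any cost-group column missing),
    ``"qaly_missing"`` (either utility missing) or the name of a column to
    treat as the indicator.  Returns one row per design term with
    coefficient, standard error, odds ratio and p-value.  Perfect separation
    or non-convergence raises rather than silently dropping terms.
    """
    if outcome == "qaly_missing":
        y = df[["utility_baseline", "utility_6m"]].isna().any(axis=1)
    elif outcome == "total_cost_missing":
        cost_cols = [c for c in df.columns if c.startswith("cost_")]
        if not cost_cols:
            raise ValueError("no cost_* columns to derive total_cost_missing from")
        y = df[cost_cols].isna().any(axis=1)
    else:
        y = df[outcome].astype(bool)
    if y.all():
        raise ValueError(f"{outcome}: every row is missing; nothing to model")
    if not y.any():
        raise ValueError(f"{outcome}: no missingness observed")

    covariates = covariates or [
        c for c in DEFAULT_DIAGNOSTIC_COVARIATES if c in df.columns
    ]
    X = _design(df, covariates)
    keep = X.notna().all(axis=1)
    try:
        res = sm.Logit(y[keep].astype(float), X[keep]).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on hard separation
        raise RuntimeError(
            f"logistic missingness model failed (possible perfect separation): {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 15:
        raise RuntimeError(
            "logistic missingness model did not converge cleanly — "
            "likely perfect separation on some covariate"
        )
    return pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "odds_ratio": np.exp(res.params),
            "p_value": res.pvalues,
        }
    )


def impute_baseline_simple(df: pd.DataFrame,
                           continuous: list[str] | None = None,
                           categorical: list[str] | None = None) -> pd.DataFrame:
    """Mean-impute continuous and mode-impute categorical baseline columns.

    Mode ties break toward the lowest category in sort order.  A column with
    no observed values raises.  Columns without missingness pass through
    unchanged.
    """
    out = df.copy()
    if continuous is None:
        continuous = [c for c in ["age_years", "comorbidity_count",
                                  "utility_baseline", "gds_baseline"]
                      if c in df.columns]
    if categorical is None:
        categorical = [c for c in ["sex", "ethnicity", "living_alone", "education"]
                       if c in df.columns]
    for c in continuous:
        obs = out[c].dropna()
        if obs.empty:
            raise ValueError(f"cannot mean-impute {c!r}: no observed values")
        out[c] = out[c].fillna(obs.mean())
    for c in categorical:
        obs = out[c].dropna()
        if obs.empty:
            raise ValueError(f"cannot mode-impute {c!r}: no observed values")
        counts = obs.value_counts()
        top = counts.max()
        mode = sorted(counts[counts == top].index)[0]
        out[c] = out[c].fillna(mode)
    return out


@dataclass
class ImputationConfig:
    """MICE-PMM settings; defaults follow common applied practice
    (m chosen >= the worst-case percentage of missing data)."""

    m_imputations: int = 40
    knn: int = 5
    by_arm: bool = True
    predictors: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    seed: int = 0
    max_iterations: int = 10

    def validate(self) -> None:
        if self.knn < 1:
            raise ValueError("knn must be >= 1")
        if self.m_imputations < 2:
            raise ValueError("m_imputations must be >= 2")
        if not self.predictors:
            raise ValueError("predictors must be non-empty")


def check_m_rule_of_thumb(df: pd.DataFrame, targets: list[str], m: int) -> bool:
    """White's rule of thumb: m >= highest percentage of missing data."""
    worst = max(100.0 * df[t].isna().mean() for t in targets)
    return m >= worst


@dataclass
class CompletedDatasetStack:
    """m completed copies of the analysis table plus imputation provenance.

    ``mask`` marks which (row, target-column) cells were imputed; observed
    cells are identical across all m datasets by construction.
    """

    datasets: list
    mask: pd.DataFrame
    config: ImputationConfig
    seed: int
    converged: bool = True

    @property
    def m(self) -> int:
        return len(self.datasets)

    def restrict(self, row_mask: pd.Series) -> "CompletedDatasetStack":
        """Row-subset every completed dataset and the mask (e.g. a GDS band)."""
        return CompletedDatasetStack(
            datasets=[d[row_mask].copy() for d in self.datasets],
            mask=self.mask[row_mask].copy(),
            config=self.config,
            seed=self.seed,
            converged=self.converged,
        )

    def write(self, path) -> None:
        """Serialise as one long CSV with an imputation index column."""
        long = pd.concat(
            [d.assign(imputation=i + 1) for i, d in enumerate(self.datasets)],
            ignore_index=True,
        )
        long.to_csv(path, index=False)


def _pmm_fill(sub: pd.DataFrame, targets: list[str], base_X: pd.DataFrame,
              knn: int, max_iterations: int,
              rng: np.random.Generator) -> tuple[pd.DataFrame, bool]:
    """One chained-equations pass over one arm; returns (completed, converged)."""
    work = sub.copy()
    miss = {t: sub[t].isna().to_numpy() for t in targets}
    # initialise missing cells with random observed draws
    for t in targets:
        obs_vals = sub[t].dropna().to_numpy()
        n_miss = int(miss[t].sum())
        if n_miss:
            work.loc[miss[t], t] = rng.choice(obs_vals, size=n_miss, replace=True)

    prev_means = None
    converged = False
    Xbase = base_X.to_numpy(float)
    for _ in range(max_iterations):
        for t in sorted(targets):
            if not miss[t].any():
                continue
            others = [o for o in sorted(targets) if o != t]
            X = np.column_stack([Xbase] + [work[o].to_numpy(float) for o in others]) \
                if others else Xbase
            y = work[t].to_numpy(float)
            obs = ~miss[t]
            beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
            pred = X @ beta
            pred_obs = pred[obs]
            donor_vals = sub[t].to_numpy(float)[obs]
            obs_pos = np.flatnonzero(obs)
            filled = np.empty(int(miss[t].sum()))
            for j, i in enumerate(np.flatnonzero(miss[t])):
                d = np.abs(pred_obs - pred[i])
                order = np.lexsort((obs_pos, d))[:knn]
                filled[j] = donor_vals[order[rng.integers(len(order))]]
            work.loc[miss[t], t] = filled
        means = np.array([work.loc[miss[t], t].mean() for t in sorted(targets)
                          if miss[t].any()])
        if prev_means is not None:
            scale = np.array([max(sub[t].dropna().std(), 1e-12)
                              for t in sorted(targets) if miss[t].any()])
            if np.all(np.abs(means - prev_means) < 0.5 * scale):
                converged = True
        prev_means = means
    return work, converged


def mice_pmm(df: pd.DataFrame, targets: list[str],
             config: ImputationConfig | None = None) -> CompletedDatasetStack:
    """Multiply impute ``targets`` by chained equations with PMM.

    Preconditions: predictor columns are complete (run
    :func:`impute_baseline_simple` first) and, within each arm, every target
    has at least ``knn`` observed donors.  Chains for the m imputations are
    independent (fresh random start each) and the whole stack is
    reproducible from ``config.seed``.
    """
    config = config or ImputationConfig()
    config.validate()
    predictors = [p for p in config.predictors if p in df.columns and p not in targets]
    if df[predictors].isna().any().any():
        raise ValueError("predictors contain missing values; complete them first")
    arms = df["arm"].unique() if config.by_arm else ["<all>"]
    for arm in arms:
        sub = df if arm == "<all>" else df[df["arm"] == arm]
        for t in targets:
            n_obs = sub[t].notna().sum()
            if n_obs < config.knn:
                raise ValueError(
                    f"target {t!r} has only {n_obs} observed donors in arm "
                    f"{arm!r}; need at least knn={config.knn}"
                )

    mask = df[targets].isna()
    seeds = np.random.SeedSequence(config.seed).spawn(config.m_imputations)
    datasets = []
    all_converged = True
    for m_seed in seeds:
        rng = np.random.default_rng(m_seed)
        completed = df.copy()
        for arm in arms:
            rows = slice(None) if arm == "<all>" else (df["arm"] == arm)
            sub = df[rows] if arm != "<all>" else df
            base_X = _design(sub, predictors)
            filled, ok = _pmm_fill(sub, targets, base_X, config.knn,
                                   config.max_iterations, rng)
            all_converged &= ok
            completed.loc[filled.index, targets] = filled[targets]
        datasets.append(completed)
    if not all_converged:
        logger.warning("MICE chain means still moving after %d iterations",
                       config.max_iterations)
    return CompletedDatasetStack(datasets=datasets, mask=mask, config=config,
                                 seed=config.seed, converged=all_converged)


# -- pattern-mixture MNAR scenarios ------------------------------------------

from .synthetic_cohort import ARM_CONTROL, ARM_TREATED  # noqa: E402


@dataclass(frozen=True)
class MnarScenario:
    """Multiplicative shifts applied to imputed cells, per arm.

    ``utility_scale``/``cost_scale`` map arm label -> multiplier (1.0 means
    untouched).  Only cells flagged in the stack's imputed mask are scaled;
    observed data are never modified.
    """

    name: str
    utility_scale: dict
    cost_scale: dict


def build_scenario_grid(scale: float = 0.10) -> list[MnarScenario]:
    """The seven standard pattern-mixture scenarios at a given scale.

    (a) utility reduction in both arms; (b) cost increase in both arms;
    (c) both; (d)/(e) utility reduction in the treated / control arm only;
    (f)/(g) cost increase in the treated / control arm only.
    """
    u, c = 1.0 - scale, 1.0 + scale
    both_u = {ARM_CONTROL: u, ARM_TREATED: u}
    both_c = {ARM_CONTROL: c, ARM_TREATED: c}
    ones_u = {ARM_CONTROL: 1.0, ARM_TREATED: 1.0}
    ones_c = {ARM_CONTROL: 1.0, ARM_TREATED: 1.0}
    return [
        MnarScenario("a", both_u, dict(ones_c)),
        MnarScenario("b", dict(ones_u), both_c),
        MnarScenario("c", both_u, both_c),
        MnarScenario("d", {ARM_CONTROL: 1.0, ARM_TREATED: u}, dict(ones_c)),
        MnarScenario("e", {ARM_CONTROL: u, ARM_TREATED: 1.0}, dict(ones_c)),
        MnarScenario("f", dict(ones_u), {ARM_CONTROL: 1.0, ARM_TREATED: c}),
        MnarScenario("g", dict(ones_u), {ARM_CONTROL: c, ARM_TREATED: 1.0}),
    ]


def apply_mnar_scenario(stack: CompletedDatasetStack, scenario: MnarScenario,
                        utility_cols: tuple = ("utility_baseline", "utility_6m"),
                        cost_cols: tuple | None = None) -> CompletedDatasetStack:
    """Scale imputed utility/cost cells by the scenario's per-arm multipliers.

    Scaled utilities are clamped back into the valid index range (a clamp is
    logged); observed cells and the mask are untouched.  Returns a new stack.
    """
    if cost_cols is None:
        cost_cols = tuple(c for c in stack.mask.columns if c.startswith("cost_"))
    known_arms = set(stack.datasets[0]["arm"].unique())
    for d in (scenario.utility_scale, scenario.cost_scale):
        unknown = set(d) - known_arms
        if unknown:
            raise ValueError(f"scenario references unknown arm(s) {sorted(unknown)}")

    new_datasets = []
    n_clamped = 0
    for ds in stack.datasets:
        out = ds.copy()
        for arm, scale in scenario.utility_scale.items():
            if scale == 1.0:
                continue
            rows = out["arm"] == arm
            for col in utility_cols:
                if col not in stack.mask.columns:
                    continue
                cells = rows & stack.mask[col]
                scaled = out.loc[cells, col] * scale
                clamped = scaled.clip(UTILITY_FLOOR, UTILITY_CEIL)
                n_clamped += int((scaled != clamped).sum())
                out.loc[cells, col] = clamped
        for arm, scale in scenario.cost_scale.items():
            if scale == 1.0:
                continue
            rows = out["arm"] == arm
            for col in cost_cols:
                cells = rows & stack.mask[col]
                out.loc[cells, col] = out.loc[cells, col] * scale
        new_datasets.append(out)
    if n_clamped:
        logger.info("MNAR scenario %s: clamped %d scaled utilities to range",
                    scenario.name, n_clamped)
    return CompletedDatasetStack(datasets=new_datasets, mask=stack.mask.copy(),
                                 config=stack.config, seed=stack.seed,
                                 converged=stack.converged)
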