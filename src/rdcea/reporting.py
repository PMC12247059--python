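"""Pipeline orchestration and export of the analysis outputs.

Ties the stages together in the order the analysis runs: cohort ->
costing (grouped, NaN-propagating) -> analysis dataset -> baseline simple
imputation -> MICE-PMM by arm -> derived QALYs and perspective totals ->
adjusted SUR + bootstrap -> results.  Four analysis families are produced:

* base case: NHS+PSS perspective on the imputed stack;
* complete case: only participants fully observed on costs and utilities at
  both time points (the arm ratio is deliberately *not* rebalanced);
* societal perspective on the imputed stack;
* the seven MNAR pattern-mixture scenarios.

Analysis follows intention-to-treat: every participant stays in the arm
implied by their baseline score.  Every exported file set carries a
provenance block (seed, config hash), and re-running with the same config
reproduces byte-identical CSV bodies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import costing
from .cea import (
    DEFAULT_LAMBDA_GRID,
    CeaResult,
    SureSpec,
    run_base_case,
)
from .costing import (
    PERSPECTIVE_NHS_PSS,
    PERSPECTIVE_SOCIETAL,
    UnitCostTable,
    cost_cohort,
    group_total,
)
from .imputation import (
    CompletedDatasetStack,
    ImputationConfig,
    apply_mnar_scenario,
    build_scenario_grid,
    impute_baseline_simple,
    mice_pmm,
)
from .outcomes import qaly_auc
from .subgroup import GdsBand, default_bands, run_subgroup_suite
from .synthetic_cohort import Cohort, CohortConfig, simulate_cohort

logger = logging.getLogger("rdcea")

COVARIATES = ["age_years", "sex", "ethnicity", "living_alone", "education",
              "comorbidity_count"]


@dataclass
class RunConfig:
    """End-to-end run settings; serialisable to/from YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    perspective: str = PERSPECTIVE_NHS_PSS
    n_bootstrap: int = 1000
    lambda_max: float = 50_000.0
    lambda_step: float = 1_000.0
    mnar_scale: float = 0.10
    bands: list | None = None
    seed: int = 0
    output_dir: str = "results"

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.arange(0.0, self.lambda_max + self.lambda_step / 2,
                         self.lambda_step)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def build_analysis_dataset(cohort: Cohort,
                           cost_table: UnitCostTable | None = None) -> pd.DataFrame:
    """One row per participant: covariates, utilities, grouped costs.

    Costs are aggregated to the imputation-level groups at both time points;
    cells belonging to a missing questionnaire block are NaN.  Derived
    quantities (QALYs, perspective totals) are *not* added here — they are
    recomputed after imputation (and after any MNAR scaling of imputed
    cells).
    """
    table = cost_table or costing.default_unit_cost_table()
    df = cohort.participants
    base = df[["id", "arm", "gds_baseline"] + COVARIATES
              + ["utility_baseline", "utility_6m"]].copy()
    costs_bl = cost_cohort(cohort, table, "baseline")
    costs_6m = cost_cohort(cohort, table, "6m")
    out = pd.concat([base, costs_bl, costs_6m], axis=1)
    logger.info("analysis dataset: %d participants, %d with complete 6m costs",
                len(out), int(costs_6m.notna().all(axis=1).sum()))
    return out


def _derive(df: pd.DataFrame, perspective: str) -> pd.DataFrame:
    """Recompute QALYs and perspective totals from (possibly imputed) cells."""
    out = df.copy()
    out["qaly"] = qaly_auc(out["utility_baseline"].to_numpy(),
                           out["utility_6m"].to_numpy())
    out["baseline_total_cost"] = group_total(out, "baseline", perspective)
    out["total_cost_6m"] = group_total(out, "6m", perspective)
    return out


def finalize_stack(stack: CompletedDatasetStack,
                   perspective: str) -> CompletedDatasetStack:
    """Attach derived columns to every completed dataset."""
    return CompletedDatasetStack(
        datasets=[_derive(d, perspective) for d in stack.datasets],
        mask=stack.mask, config=stack.config, seed=stack.seed,
        converged=stack.converged,
    )


def impute_cohort(analysis: pd.DataFrame,
                  config: ImputationConfig | None = None) -> CompletedDatasetStack:
    """Simple-impute baseline covariates, then MICE-PMM costs and utilities."""
    config = config or ImputationConfig()
    completed_baseline = impute_baseline_simple(
        analysis, continuous=[c for c in ["age_years", "comorbidity_count"]
                              if c in analysis.columns],
        categorical=[c for c in ["sex", "ethnicity", "living_alone", "education"]
                     if c in analysis.columns],
    )
    targets = [c for c in analysis.columns
               if (c.startswith("cost_") or c.startswith("utility_"))]
    targets = [t for t in targets if completed_baseline[t].isna().any()]
    if not targets:
        # nothing to impute: a stack of m identical copies
        m = config.m_imputations
        return CompletedDatasetStack(
            datasets=[completed_baseline.copy() for _ in range(m)],
            mask=completed_baseline[
                [c for c in analysis.columns
                 if c.startswith("cost_") or c.startswith("utility_")]
            ].isna(),
            config=config, seed=config.seed,
        )
    return mice_pmm(completed_baseline, targets, config)


def complete_case_stack(analysis: pd.DataFrame, perspective: str,
                        config: ImputationConfig | None = None
                        ) -> CompletedDatasetStack:
    """Single-'imputation' stack of the fully observed participants.

    Completeness is judged on the columns the chosen perspective analyses:
    both utilities plus the perspective's cost groups at both time points.
    The arm ratio is whatever completeness leaves — it is not rebalanced.
    """
    groups = list(costing.NHS_PSS_GROUPS)
    if perspective == PERSPECTIVE_SOCIETAL:
        groups += costing.SOCIETAL_ONLY_GROUPS
    cols = ["utility_baseline", "utility_6m"] + [
        c for c in analysis.columns
        if any(c == f"cost_{g}_{t}" for g in groups for t in ("baseline", "6m"))
    ]
    keep = analysis[cols].notna().all(axis=1)
    cc = analysis[keep].copy()
    cc = impute_baseline_simple(cc)
    logger.info("complete case: %d of %d participants retained",
                len(cc), len(analysis))
    mask = cc[[c for c in cols]].isna()
    return CompletedDatasetStack(datasets=[cc],
                                 mask=mask,
                                 config=config or ImputationConfig(),
                                 seed=0)


@dataclass
class ResultBundle:
    """Everything one `analyse` invocation produces."""

    base_case: CeaResult
    complete_case: CeaResult
    societal: CeaResult
    mnar: dict                      # scenario name -> CeaResult
    analysis: pd.DataFrame          # pre-imputation analysis dataset
    stack: CompletedDatasetStack    # imputed (un-finalized) stack
    config: RunConfig


def cmd_simulate(config: RunConfig, output_dir: str | Path | None = None) -> Cohort:
    """Generate and (optionally) write the synthetic cohort."""
    cohort = simulate_cohort(config.cohort)
    if output_dir is not None:
        cohort.write(output_dir)
    return cohort


def cmd_analyse(cohort: Cohort, config: RunConfig,
                cost_table: UnitCostTable | None = None) -> ResultBundle:
    """Run the four analysis families on one cohort."""
    spec = SureSpec()
    grid = config.lambda_grid
    analysis = build_analysis_dataset(cohort, cost_table)
    stack = impute_cohort(analysis, config.imputation)

    base = run_base_case(finalize_stack(stack, PERSPECTIVE_NHS_PSS), spec,
                         B=config.n_bootstrap, lambda_grid=grid,
                         seed=config.seed)
    cc = run_base_case(
        finalize_stack(complete_case_stack(analysis, PERSPECTIVE_NHS_PSS,
                                           config.imputation),
                       PERSPECTIVE_NHS_PSS),
        spec, B=config.n_bootstrap, lambda_grid=grid, seed=config.seed)
    soc = run_base_case(finalize_stack(stack, PERSPECTIVE_SOCIETAL), spec,
                        B=config.n_bootstrap, lambda_grid=grid,
                        seed=config.seed)
    mnar = {}
    for scenario in build_scenario_grid(config.mnar_scale):
        scaled = apply_mnar_scenario(stack, scenario)
        mnar[scenario.name] = run_base_case(
            finalize_stack(scaled, PERSPECTIVE_NHS_PSS), spec,
            B=config.n_bootstrap, lambda_grid=grid, seed=config.seed)
    return ResultBundle(base_case=base, complete_case=cc, societal=soc,
                        mnar=mnar, analysis=analysis, stack=stack,
                        config=config)


def cmd_subgroup(bundle: ResultBundle,
                 bands: list[GdsBand] | None = None) -> tuple[dict, pd.DataFrame]:
    """Per-band CEA plus the pooled long-format CEAC table."""
    config = bundle.config
    cutoff = config.cohort.gds_cutoff
    bands = bands or default_bands(cutoff)
    return run_subgroup_suite(
        finalize_stack(bundle.stack, config.perspective),
        bands=bands, B=config.n_bootstrap,
        lambda_grid=config.lambda_grid, seed=config.seed, cutoff=cutoff)


def utility_qaly_table(stack: CompletedDatasetStack,
                       complete_case: CompletedDatasetStack) -> pd.DataFrame:
    """By-arm mean utilities and QALYs, imputed and complete-case variants."""
    rows = []
    for label, st in [("imputed", stack), ("complete_case", complete_case)]:
        per_ds = []
        for ds in st.datasets:
            d = _derive(ds, PERSPECTIVE_NHS_PSS) if "qaly" not in ds else ds
            per_ds.append(d.groupby("arm")[
                ["utility_baseline", "utility_6m", "qaly"]].mean())
        mean = sum(per_ds) / len(per_ds)
        mean = mean.reset_index()
        mean.insert(0, "population", label)
        rows.append(mean)
    return pd.concat(rows, ignore_index=True)


def cost_table_by_arm(stack: CompletedDatasetStack,
                      complete_case: CompletedDatasetStack) -> pd.DataFrame:
    """By-arm mean 6-month costs per group plus both perspective totals."""
    rows = []
    for label, st in [("imputed", stack), ("complete_case", complete_case)]:
        per_ds = []
        for ds in st.datasets:
            d = ds.copy()
            d["total_nhs_pss"] = group_total(d, "6m", PERSPECTIVE_NHS_PSS)
            d["total_societal"] = group_total(d, "6m", PERSPECTIVE_SOCIETAL)
            cols = [c for c in d.columns if c.startswith("cost_") and
                    c.endswith("_6m")] + ["total_nhs_pss", "total_societal"]
            per_ds.append(d.groupby("arm")[cols].mean())
        mean = (sum(per_ds) / len(per_ds)).reset_index()
        mean.insert(0, "population", label)
        rows.append(mean)
    return pd.concat(rows, ignore_index=True)


def cmd_report(bundle: ResultBundle, output_dir: str | Path) -> dict:
    """Write tables and figure datasets; returns the summary dict."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = bundle.config
    cc_stack = complete_case_stack(bundle.analysis, PERSPECTIVE_NHS_PSS,
                                   config.imputation)

    utility_qaly_table(bundle.stack, cc_stack).to_csv(
        out / "table_utility_qaly.csv", index=False)
    cost_table_by_arm(
        finalize_stack(bundle.stack, PERSPECTIVE_NHS_PSS),
        finalize_stack(cc_stack, PERSPECTIVE_NHS_PSS),
    ).to_csv(out / "table_costs.csv", index=False)

    summary = {}
    for name, res in [("base_case", bundle.base_case),
                      ("complete_case", bundle.complete_case),
                      ("societal", bundle.societal),
                      *[(f"mnar_{k}", v) for k, v in bundle.mnar.items()]]:
        res.replicates.to_csv(out / f"ce_plane_{name}.csv", index=False)
        res.ceac.to_frame().to_csv(out / f"ceac_{name}.csv", index=False)
        summary[name] = res.summary()

    provenance = {"seed": config.seed, "config_hash": config.hash()}
    summary["provenance"] = provenance
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    config.to_yaml(out / "config.yaml")
    return summary
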