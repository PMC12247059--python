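"""Assignment-score-band subgroups and baseline balance checks.

Because allocation follows the depression-score cutoff, participants far
below the cutoff differ systematically from those far above it.  Restricting
the analysis to symmetric score bands around the cutoff (0-9, 1-8, 2-7, 3-6,
4-5 for a cutoff of 5) retains increasingly comparable participants —
approaching the local-randomisation reading of the design — at the price of
sample size.  Balance across arms within a band is checked descriptively
with Welch two-sample t-tests (continuous covariates) and chi-squared tests
on the arm-by-category table (categorical covariates); no multiple-testing
adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cea import DEFAULT_LAMBDA_GRID, CeaResult, SureSpec, run_base_case
from .imputation import CompletedDatasetStack


@dataclass(frozen=True)
class GdsBand:
    """Inclusive baseline-score range retained in a subgroup analysis."""

    low: int
    high: int

    def validate(self, cutoff: int = 5) -> None:
        if not (0 <= self.low <= self.high <= 15):
            raise ValueError("band must satisfy 0 <= low <= high <= 15")
        if not (self.low <= cutoff - 1 and self.high >= cutoff):
            raise ValueError(
                f"band {self.low}-{self.high} must contain scores on both "
                f"sides of the cutoff {cutoff}"
            )

    @property
    def name(self) -> str:
        return f"{self.low}-{self.high}"


def default_bands(cutoff: int = 5) -> list[GdsBand]:
    """Symmetric bands narrowing toward the cutoff: 0-9, 1-8, ..., 4-5."""
    bands = []
    for w in range(cutoff - 1, -1, -1):
        band = GdsBand(cutoff - 1 - w, cutoff + w)
        if band.high <= 15:
            bands.append(band)
    return bands


def restrict_band(df: pd.DataFrame, band: GdsBand,
                  cutoff: int = 5) -> pd.DataFrame:
    """Participants with baseline score inside the band; arms unchanged."""
    band.validate(cutoff)
    return df[(df["gds_baseline"] >= band.low)
              & (df["gds_baseline"] <= band.high)]


DEFAULT_CONTINUOUS = ["age_years", "gds_baseline", "comorbidity_count",
                      "utility_baseline", "baseline_total_cost"]
DEFAULT_CATEGORICAL = ["sex", "ethnicity", "living_alone", "education"]


def balance_tests(df: pd.DataFrame,
                  continuous: list[str] | None = None,
                  categorical: list[str] | None = None,
                  yates_2x2: bool = False) -> pd.DataFrame:
    """Arm-balance table: Welch t-tests and chi-squared tests per covariate.

    Returns one row per covariate with the test name, statistic, p-value and
    per-arm summaries (means for continuous, modal share for categorical).
    A covariate constant in both arms is skipped with ``test='skipped'``.
    """
    arms = sorted(df["arm"].unique())
    if len(arms) < 2:
        raise ValueError("both arms must be non-empty")
    if continuous is None:
        continuous = [c for c in DEFAULT_CONTINUOUS if c in df.columns]
    if categorical is None:
        categorical = [c for c in DEFAULT_CATEGORICAL if c in df.columns]
    rows = []
    for c in continuous:
        groups = [df.loc[df["arm"] == a, c].dropna() for a in arms]
        summaries = {f"mean_{a}": g.mean() for a, g in zip(arms, groups)}
        if df[c].nunique(dropna=True) < 2:
            rows.append(dict(covariate=c, test="skipped", statistic=np.nan,
                             p_value=np.nan, **summaries))
            continue
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        rows.append(dict(covariate=c, test="welch_t", statistic=float(stat),
                         p_value=float(p), **summaries))
    for c in categorical:
        tab = pd.crosstab(df["arm"], df[c])
        summaries = {
            f"mode_share_{a}": (tab.loc[a] / tab.loc[a].sum()).max()
            for a in arms if a in tab.index
        }
        if tab.shape[1] < 2:
            rows.append(dict(covariate=c, test="skipped", statistic=np.nan,
                             p_value=np.nan, **summaries))
            continue
        correction = yates_2x2 and tab.shape == (2, 2)
        stat, p, _, _ = stats.chi2_contingency(tab, correction=correction)
        rows.append(dict(covariate=c, test="chi_squared", statistic=float(stat),
                         p_value=float(p), **summaries))
    return pd.DataFrame(rows)


def run_subgroup_suite(stack: CompletedDatasetStack,
                       bands: list[GdsBand] | None = None,
                       spec: SureSpec | None = None,
                       B: int = 1000,
                       lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                       seed: int | None = 0,
                       cutoff: int = 5) -> tuple[dict, pd.DataFrame]:
    """Run the full adjusted CEA within each score band.

    Returns ``(results, pooled)`` where ``results`` maps band name ->
    :class:`CeaResult` and ``pooled`` is a long table (band, lambda,
    probability) for overlaying the subgroup CEACs on one plot.
    """
    bands = bands if bands is not None else default_bands(cutoff)
    spec = spec or SureSpec()
    base = stack.datasets[0]
    results: dict[str, CeaResult] = {}
    pooled_rows = []
    for band in bands:
        band.validate(cutoff)
        keep = (base["gds_baseline"] >= band.low) & (base["gds_baseline"] <= band.high)
        sub = stack.restrict(keep)
        counts = sub.datasets[0]["arm"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError(f"band {band.name} leaves an arm empty or near-empty")
        res = run_base_case(sub, spec, B=B, lambda_grid=lambda_grid, seed=seed)
        results[band.name] = res
        frame = res.ceac.to_frame()
        frame.insert(0, "band", band.name)
        pooled_rows.append(frame)
    pooled = pd.concat(pooled_rows, ignore_index=True)
    return results, pooled
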