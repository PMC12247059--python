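"""Covariate-adjusted incremental cost-effectiveness estimation.

The core estimator is a two-equation seemingly-unrelated-regression (SUR)
system,

    cost_6m = a0 + a1*treated + a'z + e_c
    QALY    = b0 + b1*treated + b'z + e_q,

with correlated errors (e_c, e_q) and the same adjusters z in both
equations: baseline age, sex, ethnicity, living arrangement, education,
comorbidity count, baseline costs and baseline utility.  (a1, b1) are the
adjusted incremental cost and incremental QALY of the intervention.
Estimation is feasible GLS; with identical regressors in both equations the
GLS solution coincides exactly with per-equation least squares — a
property the test suite uses as an oracle.

Uncertainty combines multiple imputation with a nonparametric bootstrap:
participants are resampled with replacement (stratified by arm, preserving
the design's arm imbalance), the system is refitted on each of the m
completed datasets restricted to the resample, and the m coefficient pairs
are averaged into one (delta_cost, delta_QALY) replicate.  Percentile
intervals, the ICER/dominance verdict, the cost-effectiveness plane and the
cost-effectiveness acceptability curve (CEAC: P(lambda*dQALY - dCost > 0))
all derive from the replicate cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imputation import CompletedDatasetStack, _design
from .synthetic_cohort import ARM_TREATED

DEFAULT_ADJUSTERS = [
    "age_years", "sex", "ethnicity", "living_alone", "education",
    "comorbidity_count", "baseline_total_cost", "utility_baseline",
]

#: default willingness-to-pay grid, GBP per QALY (covers the conventional
#: UK decision thresholds of 20k-30k)
DEFAULT_LAMBDA_GRID = np.arange(0, 50_001, 1_000)


@dataclass
class SureSpec:
    """Column roles for the two-equation system."""

    cost_col: str = "total_cost_6m"
    qaly_col: str = "qaly"
    arm_col: str = "arm"
    treated_level: str = ARM_TREATED
    adjusters: list[str] = field(default_factory=lambda: list(DEFAULT_ADJUSTERS))


@dataclass
class SureFit:
    delta_cost: float
    delta_qaly: float
    se_delta_cost: float
    se_delta_qaly: float
    params: pd.DataFrame        # one column per equation
    resid_cov: np.ndarray       # 2x2 residual covariance
    nobs: int


def design_matrix(df: pd.DataFrame, spec: SureSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept + treated indicator + reference-coded adjusters."""
    X = _design(df, [c for c in spec.adjusters if c in df.columns])
    treated = (df[spec.arm_col] == spec.treated_level).astype(float)
    X.insert(1, "treated", treated)
    return X.to_numpy(float), list(X.columns)


def _sur_fgls(X_list: list[np.ndarray], y_list: list[np.ndarray]):
    """One-step feasible GLS for an M-equation SUR system.

    Per-equation OLS residuals estimate the error covariance; the stacked
    GLS normal equations are then solved blockwise.  Returns (list of
    coefficient vectors, residual covariance, per-equation GLS covariance
    blocks).
    """
    n = X_list[0].shape[0]
    M = len(X_list)
    betas_ols = []
    resid = np.empty((n, M))
    for j, (X, y) in enumerate(zip(X_list, y_list)):
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        betas_ols.append(b)
        resid[:, j] = y - X @ b
    k_total = sum(X.shape[1] for X in X_list)
    sigma = resid.T @ resid / (n - 0)  # ML-style divisor; only ratios matter
    if np.linalg.cond(sigma) > 1e12:
        raise np.linalg.LinAlgError("singular residual covariance")
    S = np.linalg.inv(sigma)
    A = np.zeros((k_total, k_total))
    bvec = np.zeros(k_total)
    offs = np.cumsum([0] + [X.shape[1] for X in X_list])
    for i in range(M):
        for j in range(M):
            A[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = (
                S[i, j] * X_list[i].T @ X_list[j]
            )
        bvec[offs[i]:offs[i + 1]] = sum(
            S[i, j] * X_list[i].T @ y_list[j] for j in range(M)
        )
    beta = np.linalg.solve(A, bvec)
    cov = np.linalg.inv(A)
    betas = [beta[offs[i]:offs[i + 1]] for i in range(M)]
    covs = [cov[offs[i]:offs[i + 1], offs[i]:offs[i + 1]] for i in range(M)]
    return betas, sigma, covs


def fit_sure(df: pd.DataFrame, spec: SureSpec | None = None) -> SureFit:
    """Fit the cost/QALY SUR system on one completed dataset.

    Requires no missing cells in the modelled columns, both arms present,
    and a full-rank design.  The treated-indicator coefficients are the
    adjusted incremental cost and QALY.
    """
    spec = spec or SureSpec()
    cols = [spec.cost_col, spec.qaly_col]
    if df[cols].isna().any().any():
        raise ValueError("missing cost/QALY cells; impute before fitting")
    arm_counts = df[spec.arm_col].value_counts()
    if len(arm_counts) < 2 or arm_counts.min() < 2:
        raise ValueError("need at least 2 participants in each arm")
    X, names = design_matrix(df, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    y_c = df[spec.cost_col].to_numpy(float)
    y_q = df[spec.qaly_col].to_numpy(float)
    betas, sigma, covs = _sur_fgls([X, X], [y_c, y_q])
    i = names.index("treated")
    params = pd.DataFrame({"cost": betas[0], "qaly": betas[1]}, index=names)
    return SureFit(
        delta_cost=float(betas[0][i]),
        delta_qaly=float(betas[1][i]),
        se_delta_cost=float(np.sqrt(covs[0][i, i])),
        se_delta_qaly=float(np.sqrt(covs[1][i, i])),
        params=params,
        resid_cov=sigma,
        nobs=len(df),
    )


def _stack_arrays(stack: CompletedDatasetStack, spec: SureSpec):
    """Per-dataset (X, Y) numpy arrays plus arm strata for fast refits."""
    arrays = []
    for ds in stack.datasets:
        X, names = design_matrix(ds, spec)
        Y = ds[[spec.cost_col, spec.qaly_col]].to_numpy(float)
        arrays.append((X, Y))
    arm = stack.datasets[0][spec.arm_col].to_numpy()
    strata = [np.flatnonzero(arm == a) for a in np.unique(arm)]
    return arrays, strata


def bootstrap_cea(stack: CompletedDatasetStack, spec: SureSpec | None = None,
                  B: int = 1000, seed: int | None = 0,
                  identity_resample: bool = False,
                  max_redraws: int = 100) -> pd.DataFrame:
    """B bootstrap replicates of (delta_cost, delta_qaly).

    Resampling is with replacement within each arm (stratified), so every
    resample preserves the arm sizes; each replicate averages the refitted
    treated coefficients over the stack's m completed datasets.  Because the
    two equations share regressors, the SUR solution equals per-equation
    least squares, which is what each refit solves.  ``identity_resample``
    is a test hook that skips resampling so a single replicate reproduces
    the point estimate exactly.
    """
    spec = spec or SureSpec()
    if B < 1:
        raise ValueError("B must be >= 1")
    arrays, strata = _stack_arrays(stack, spec)
    n = arrays[0][0].shape[0]
    rng = np.random.default_rng(seed)
    out = np.empty((B, 2))
    for b in range(B):
        if identity_resample:
            idx = np.arange(n)
        else:
            for _ in range(max_redraws):
                idx = np.concatenate(
                    [rng.choice(s, size=s.size, replace=True) for s in strata]
                )
                if len(strata) > 1 or len(np.unique(idx)) > 1:
                    break
            else:
                raise RuntimeError("could not draw a two-arm resample")
        acc = np.zeros(2)
        for X, Y in arrays:
            beta, *_ = np.linalg.lstsq(X[idx], Y[idx], rcond=None)
            acc += beta[1]  # treated indicator is column 1 by construction
        out[b] = acc / len(arrays)
    return pd.DataFrame(
        {"replicate": np.arange(1, B + 1),
         "delta_cost": out[:, 0], "delta_qaly": out[:, 1]}
    )


@dataclass(frozen=True)
class IcerResult:
    icer: float           # NaN when the ratio is not interpretable
    label: str            # dominant | dominated | tradeoff_NE | tradeoff_SW
    #                     # | undefined_ratio_*


def icer_and_dominance(delta_cost: float, delta_qaly: float) -> IcerResult:
    """Classify the incremental pair and compute the ICER where meaningful.

    More costly and less effective -> dominated; cheaper and more effective
    -> dominant; a zero QALY difference leaves the ratio undefined; otherwise
    the ICER is reported with its cost-effectiveness-plane quadrant.
    """
    dc, de = float(delta_cost), float(delta_qaly)
    if de == 0.0:
        sign = "zero" if dc == 0 else ("positive" if dc > 0 else "negative")
        return IcerResult(float("nan"), f"undefined_ratio_cost_{sign}")
    if dc > 0 and de < 0:
        return IcerResult(float("nan"), "dominated")
    if dc < 0 and de > 0:
        return IcerResult(float("nan"), "dominant")
    return IcerResult(dc / de, "tradeoff_NE" if de > 0 else "tradeoff_SW")


@dataclass
class CEACCurve:
    """P(cost-effective) over a willingness-to-pay grid."""

    lambda_grid: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambda_grid,
                             "probability": self.probability})

    def at(self, lam: float) -> float:
        i = int(np.flatnonzero(np.asarray(self.lambda_grid) == lam)[0])
        return float(self.probability[i])


def ceac(replicates: pd.DataFrame,
         lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> CEACCurve:
    """Fraction of replicates with positive net monetary benefit at each
    lambda: P(lambda*dQALY - dCost > 0)."""
    if len(replicates) == 0:
        raise ValueError("no replicates")
    de = replicates["delta_qaly"].to_numpy()[:, None]
    dc = replicates["delta_cost"].to_numpy()[:, None]
    lam = np.asarray(lambda_grid, float)[None, :]
    prob = (lam * de - dc > 0).mean(axis=0)
    return CEACCurve(np.asarray(lambda_grid, float), prob)


def quadrant_shares(replicates: pd.DataFrame) -> dict:
    """Cost-effectiveness-plane quadrant shares across the replicate cloud."""
    dc = replicates["delta_cost"].to_numpy()
    de = replicates["delta_qaly"].to_numpy()
    n = len(replicates)
    return {
        "NE": float(((de > 0) & (dc >= 0)).sum() / n),
        "NW": float(((de <= 0) & (dc >= 0)).sum() / n),
        "SW": float(((de <= 0) & (dc < 0)).sum() / n),
        "SE": float(((de > 0) & (dc < 0)).sum() / n),
    }


@dataclass
class CeaResult:
    """Point estimates, percentile intervals, verdict, replicates and CEAC."""

    delta_cost: float
    delta_qaly: float
    ci_cost: tuple
    ci_qaly: tuple
    icer: IcerResult
    replicates: pd.DataFrame
    ceac: CEACCurve
    provenance: dict

    def summary(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_cost_ci": list(self.ci_cost),
            "delta_qaly": self.delta_qaly,
            "delta_qaly_ci": list(self.ci_qaly),
            "icer": None if np.isnan(self.icer.icer) else self.icer.icer,
            "verdict": self.icer.label,
            "quadrant_shares": quadrant_shares(self.replicates),
            **self.provenance,
        }


def run_base_case(stack: CompletedDatasetStack, spec: SureSpec | None = None,
                  B: int = 1000,
                  lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                  seed: int | None = 0,
                  identity_resample: bool = False) -> CeaResult:
    """Full adjusted CEA on a completed-dataset stack.

    Point estimates are the mean over the m per-dataset SUR fits; intervals
    are 2.5/97.5 bootstrap percentiles; the CEAC is computed on the same
    replicate cloud.
    """
    spec = spec or SureSpec()
    fits = [fit_sure(ds, spec) for ds in stack.datasets]
    dc = float(np.mean([f.delta_cost for f in fits]))
    de = float(np.mean([f.delta_qaly for f in fits]))
    reps = bootstrap_cea(stack, spec, B=B, seed=seed,
                         identity_resample=identity_resample)
    lo_c, hi_c = np.percentile(reps["delta_cost"], [2.5, 97.5])
    lo_q, hi_q = np.percentile(reps["delta_qaly"], [2.5, 97.5])
    return CeaResult(
        delta_cost=dc,
        delta_qaly=de,
        ci_cost=(float(lo_c), float(hi_c)),
        ci_qaly=(float(lo_q), float(hi_q)),
        icer=icer_and_dominance(dc, de),
        replicates=reps,
        ceac=ceac(reps, lambda_grid),
        provenance={"seed": seed, "B": B, "m": stack.m,
                    "n": int(len(stack.datasets[0]))},
    )
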