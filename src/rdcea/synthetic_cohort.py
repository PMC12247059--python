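"""Synthetic cohort generator for a cutoff-allocated two-arm study.

Emulates a pragmatic study in which older adults (>= 65 years) complete a
15-item geriatric depression scale (GDS-15, scores 0-15) at baseline and are
allocated deterministically by a cutoff: scores at or above the cutoff
(default 5, "at least mild depression") enter the intervention arm ("SG",
screening plus notification of the participant and their GP); scores below
stay in standard of care ("SoC").  Because allocation follows the score, the
arms are imbalanced both in size (roughly 85/15 with the default score
distribution) and in baseline health: utility and mental-health-related
resource use both worsen with the depression score, which is exactly the
confounding structure the downstream covariate-adjusted analysis has to
remove.

The generator produces, per participant: demographics and baseline
covariates, EQ-5D-style utility at baseline and 6 months (directly on the
index scale), zero-inflated right-skewed resource-use counts by category at
both time points, antidepressant medication records with occasionally
missing dose/frequency, and covariate-dependent (MAR, optionally MNAR)
missingness.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

ARM_CONTROL = "SoC"
ARM_TREATED = "SG"

UTILITY_FLOOR = -0.594  # UK EQ-5D-3L value-set floor
UTILITY_CEIL = 1.0

#: resource-use categories measured at both baseline and 6 months
CATEGORIES_BOTH = [
    "community_care",      # GP / nurse / other primary-care contacts
    "hospital_care",       # overnight in-patient nights (incl. A&E admissions)
    "social_care",         # social worker / paid home care worker visits
    "travel",              # trips to appointments (societal)
    "productivity_hours",  # hours of paid work lost (societal)
    "charity_hours",       # hours of charity support (societal)
    "private_care",        # private mental-health contacts (societal)
    "self_care",           # self-care items/activities (societal)
]
#: categories measured only at the 6-month follow-up
CATEGORIES_6M_ONLY = ["mental_health"]  # NHS mental-health service contacts

EDUCATION_LEVELS = ["none", "gcse", "a_level", "degree"]

DRUGS = ["citalopram", "fluoxetine", "sertraline", "mirtazapine"]
#: typical adult daily dose in mg, used as the generator's prescribed dose
DRUG_TYPICAL_DOSE_MG = {
    "citalopram": 20.0,
    "fluoxetine": 20.0,
    "sertraline": 50.0,
    "mirtazapine": 30.0,
}


@dataclass(frozen=True)
class TwoPartCounts:
    """Two-part count model: Bernoulli(any use) x lognormal(amount).

    The probability of any use is logistic in the baseline depression score,
    ``expit(logit_intercept + logit_gds_slope * gds)``; positive counts are
    ``max(1, round(LogNormal(log_mean, log_sd)))``, giving the zero-inflated
    right-skewed pattern typical of mental-health resource use.
    """

    logit_intercept: float
    logit_gds_slope: float
    log_mean: float
    log_sd: float


def _default_cost_model() -> dict:
    return {
        "community_care": TwoPartCounts(-2.8, 0.30, math.log(2.0), 0.6),
        "hospital_care": TwoPartCounts(-4.5, 0.35, math.log(1.3), 0.7),
        "mental_health": TwoPartCounts(-5.0, 0.45, math.log(2.0), 0.5),
        "social_care": TwoPartCounts(-5.0, 0.30, math.log(4.0), 0.8),
        "travel": TwoPartCounts(-3.0, 0.25, math.log(2.0), 0.5),
        "productivity_hours": TwoPartCounts(-3.5, 0.20, math.log(8.0), 0.8),
        "charity_hours": TwoPartCounts(-6.5, 0.25, math.log(2.0), 0.5),
        "private_care": TwoPartCounts(-5.5, 0.20, math.log(1.5), 0.4),
        "self_care": TwoPartCounts(-3.5, 0.20, math.log(3.0), 0.7),
    }


@dataclass(frozen=True)
class BaselineUtilityModel:
    """Linear utility gradient in the depression score, clipped to range."""

    intercept: float = 0.93
    gds_slope: float = -0.028
    sd: float = 0.12


@dataclass(frozen=True)
class LogisticRule:
    """Logistic model for one missingness block.

    ``P(missing) = expit(intercept + sum coef_j * x_j [+ mnar_coef * v])``
    where the ``x_j`` are observed covariates and ``v`` is the participant's
    own (about-to-be-hidden) value of ``mnar_value_col`` — a nonzero
    ``mnar_coef`` makes the mechanism missing-not-at-random.
    """

    intercept: float
    coefficients: dict = field(default_factory=dict)
    mnar_coef: float = 0.0
    mnar_value_col: str | None = None


def _default_missingness_model() -> dict:
    # roughly 35% missing 6m utility / 30% missing 6m costs overall, with
    # women and higher depression scores more likely to be missing
    return {
        "utility_6m": LogisticRule(-0.9, {"female": 0.5, "gds_baseline": 0.08}),
        "costs_6m": LogisticRule(-1.1, {"female": 0.4, "gds_baseline": 0.06}),
        "utility_baseline": LogisticRule(-2.5),
        "costs_baseline": LogisticRule(-2.2),
        "age_years": LogisticRule(-3.9),
        "education": LogisticRule(-3.5),
    }


def _default_gds_distribution() -> np.ndarray:
    # truncated-geometric score distribution; ratio chosen so that the mass
    # at/above the cutoff of 5 is ~15.4%, reproducing an ~863/157 arm split
    # at n=1020
    w = 0.688 ** np.arange(16)
    return w / w.sum()


@dataclass
class CohortConfig:
    """Every knob of the synthetic cohort; defaults are the study conditions.

    ``treatment_effect_utility`` is the additive shift in expected 6-month
    utility for the intervention arm; with the half-year trapezoid QALY it
    corresponds to a true incremental QALY of ``0.25 *
    treatment_effect_utility``.  The default of -0.024 encodes a true
    adjusted incremental QALY of -0.006.  ``treatment_effect_community_visits``
    is the expected number of additional 6-month primary-care contacts the
    notification triggers (Poisson); with the default unit-cost table
    (GBP 40 per contact) the default 0.925 encodes a true incremental cost of
    about GBP 37.
    """

    n_participants: int = 1020
    gds_cutoff: int = 5
    gds_distribution: np.ndarray = field(default_factory=_default_gds_distribution)
    baseline_utility_model: BaselineUtilityModel = field(
        default_factory=BaselineUtilityModel
    )
    utility_drift_6m: float = -0.01
    utility_sd_6m: float = 0.10
    treatment_effect_utility: float = -0.024
    treatment_effect_community_visits: float = 0.925
    cost_model: dict = field(default_factory=_default_cost_model)
    cost_persistence_logit: float = 2.0  # 6m any-use bump for baseline users
    mental_health_utility_slope: float = 3.0  # 6m-only use vs baseline utility
    outlier_rate: float = 0.02  # P(extended stay | any in-patient use at 6m)
    outlier_nights: int = 38    # ~GBP 21.7k at the default per-night cost
    female_fraction: float = 0.48
    white_fraction: float = 0.99
    medication_logit_intercept: float = -3.5
    medication_logit_gds_slope: float = 0.30
    medication_missing_fraction: float = 0.10
    missingness_model: dict | None = field(default_factory=_default_missingness_model)
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.gds_distribution, dtype=float)
        if p.shape != (16,):
            raise ValueError("gds_distribution must have 16 entries (scores 0-15)")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("gds_distribution entries must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("gds_distribution must sum to 1 within 1e-9")
        if not 0 <= self.gds_cutoff <= 15:
            raise ValueError("gds_cutoff must lie in [0, 15]")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        below = p[: self.gds_cutoff].sum()
        if below <= 0.0 or below >= 1.0:
            raise ValueError(
                "gds_distribution must place mass on both sides of the cutoff"
            )
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be a probability")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gds_distribution"] = list(map(float, self.gds_distribution))
        return d


@dataclass
class Cohort:
    """Participant table plus long-format medication records.

    ``participants`` has one row per participant (covariates, arm, utilities,
    one count column per category and time point, ``missing_*`` flags once
    missingness has been applied); ``medications`` has one row per
    (participant, drug) with possibly-missing ``daily_dose_mg`` and
    ``days_taken``.
    """

    participants: pd.DataFrame
    medications: pd.DataFrame
    config: CohortConfig | None = None

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(directory / "participants.csv", index=False)
        self.medications.to_csv(directory / "medications.csv", index=False)
        meta = {"seed": None if self.config is None else self.config.seed}
        if self.config is not None:
            meta["config"] = self.config.to_dict()
        (directory / "cohort_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "Cohort":
        directory = Path(directory)
        participants = pd.read_csv(directory / "participants.csv")
        medications = pd.read_csv(directory / "medications.csv")
        return cls(participants=participants, medications=medications)


def count_columns(timepoint: str) -> list[str]:
    """Count-column names for ``timepoint`` in {'baseline', '6m'}."""
    if timepoint == "baseline":
        return [f"{c}_baseline" for c in CATEGORIES_BOTH]
    if timepoint == "6m":
        return [f"{c}_6m" for c in CATEGORIES_BOTH + CATEGORIES_6M_ONLY]
    raise ValueError(f"unknown timepoint {timepoint!r}")


def _draw_counts(rng: np.random.Generator, model: TwoPartCounts,
                 gds: np.ndarray, extra_logit: np.ndarray | float = 0.0) -> np.ndarray:
    p = expit(model.logit_intercept + model.logit_gds_slope * gds + extra_logit)
    any_use = rng.random(gds.size) < p
    amounts = np.maximum(
        1, np.rint(rng.lognormal(model.log_mean, model.log_sd, gds.size))
    )
    return np.where(any_use, amounts, 0.0).astype(float)


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full cohort, then apply the configured missingness.

    Returns a :class:`Cohort`; with ``config.missingness_model`` set (the
    default), cells are blanked according to the MAR/MNAR logistic rules and
    ``missing_<block>`` flag columns are added.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng, rng_missing = [np.random.default_rng(s) for s in ss.spawn(2)]
    n = config.n_participants

    gds = rng.choice(16, size=n, p=np.asarray(config.gds_distribution, float))
    treated = gds >= config.gds_cutoff

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "gds_baseline": gds.astype(int),
            "arm": np.where(treated, ARM_TREATED, ARM_CONTROL),
            "age_years": 65.0 + rng.gamma(2.0, 4.5, n),
            "sex": np.where(rng.random(n) < config.female_fraction, "female", "male"),
            "ethnicity": np.where(rng.random(n) < config.white_fraction, "white", "other"),
            "living_alone": rng.random(n) < expit(-1.2 + 0.12 * gds),
            "education": rng.choice(EDUCATION_LEVELS, size=n, p=[0.25, 0.40, 0.20, 0.15]),
            "comorbidity_count": rng.poisson(1.2 + 0.12 * gds),
        }
    )

    um = config.baseline_utility_model
    u0 = um.intercept + um.gds_slope * gds + rng.normal(0.0, um.sd, n)
    u0 = np.clip(u0, UTILITY_FLOOR, UTILITY_CEIL)
    # 6m utility follows baseline (so the confounding runs through the
    # adjusted baseline utility), plus secular drift and the arm effect
    u6 = (
        u0
        + config.utility_drift_6m
        + config.treatment_effect_utility * treated
        + rng.normal(0.0, config.utility_sd_6m, n)
    )
    df["utility_baseline"] = u0
    df["utility_6m"] = np.clip(u6, UTILITY_FLOOR, UTILITY_CEIL)

    # Baseline use worsens with the depression score; 6m use depends on the
    # score only through baseline use (and, for the 6m-only mental-health
    # category, through baseline utility).  Confounding therefore runs
    # through the baseline measures the analysis adjusts for, which is what
    # makes the configured treatment effects identifiable truths.
    for cat in CATEGORIES_BOTH:
        df[f"{cat}_baseline"] = _draw_counts(rng, config.cost_model[cat], gds)
    zero_slope = 0.0 * gds
    for cat in CATEGORIES_BOTH:
        persist = config.cost_persistence_logit * (df[f"{cat}_baseline"].to_numpy() > 0)
        model = config.cost_model[cat]
        df[f"{cat}_6m"] = _draw_counts(
            rng, TwoPartCounts(model.logit_intercept, 0.0, model.log_mean,
                               model.log_sd),
            zero_slope, persist)
    for cat in CATEGORIES_6M_ONLY:
        model = config.cost_model[cat]
        frailty = config.mental_health_utility_slope * (0.85 - u0)
        df[f"{cat}_6m"] = _draw_counts(
            rng, TwoPartCounts(model.logit_intercept, 0.0, model.log_mean,
                               model.log_sd),
            zero_slope, frailty)

    # the notification triggers extra primary-care contacts in the treated arm
    extra = rng.poisson(config.treatment_effect_community_visits, n) * treated
    df["community_care_6m"] = df["community_care_6m"] + extra

    # rare extended in-patient stays among 6m hospital users
    users = df["hospital_care_6m"].to_numpy() > 0
    outlier = users & (rng.random(n) < config.outlier_rate)
    df.loc[outlier, "hospital_care_6m"] = float(config.outlier_nights)

    # antidepressant records (6m recall)
    on_med = rng.random(n) < expit(
        config.medication_logit_intercept + config.medication_logit_gds_slope * gds
    )
    med_ids = df.loc[on_med, "id"].to_numpy()
    drugs = rng.choice(DRUGS, size=med_ids.size, p=[0.35, 0.25, 0.25, 0.15])
    days = np.clip(np.rint(rng.normal(120, 40, med_ids.size)), 14, 182)
    dose = np.array([DRUG_TYPICAL_DOSE_MG[d] for d in drugs])
    dose[rng.random(med_ids.size) < config.medication_missing_fraction] = np.nan
    days = days.astype(float)
    days[rng.random(med_ids.size) < config.medication_missing_fraction] = np.nan
    medications = pd.DataFrame(
        {"id": med_ids, "drug": drugs, "daily_dose_mg": dose, "days_taken": days}
    )

    cohort = Cohort(participants=df, medications=medications, config=config)
    if config.missingness_model is not None:
        cohort = apply_missingness(
            cohort, config.missingness_model, seed=rng_missing
        )
        cohort.config = config
    return cohort


#: cells blanked by each missingness block
MISSINGNESS_BLOCKS = {
    "utility_baseline": lambda: ["utility_baseline"],
    "utility_6m": lambda: ["utility_6m"],
    "costs_baseline": lambda: count_columns("baseline"),
    "costs_6m": lambda: count_columns("6m"),
    "age_years": lambda: ["age_years"],
    "education": lambda: ["education"],
}


def _missingness_covariate(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "female":
        return (df["sex"] == "female").to_numpy(float)
    if name not in df.columns:
        raise ValueError(f"missingness model references unknown covariate {name!r}")
    col = df[name]
    if col.dtype == bool:
        return col.to_numpy(float)
    return col.to_numpy(float)


def apply_missingness(cohort: Cohort, model: dict,
                      seed: int | np.random.Generator = 0) -> Cohort:
    """Blank cells block-wise according to per-block logistic rules.

    ``model`` maps a block name (see :data:`MISSINGNESS_BLOCKS`) to a
    :class:`LogisticRule`.  A whole block (e.g. every 6-month count column)
    is blanked together, mimicking an unreturned questionnaire section.
    Adds a boolean ``missing_<block>`` column per modelled block.  Returns a
    new cohort; the input is not modified.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    df = cohort.participants.copy()
    n = len(df)
    for block, rule in model.items():
        if block not in MISSINGNESS_BLOCKS:
            raise ValueError(f"unknown missingness block {block!r}")
        eta = np.full(n, float(rule.intercept))
        for cov, coef in rule.coefficients.items():
            eta = eta + coef * _missingness_covariate(df, cov)
        if rule.mnar_coef:
            col = rule.mnar_value_col or MISSINGNESS_BLOCKS[block]()[0]
            eta = eta + rule.mnar_coef * df[col].to_numpy(float)
        missing = rng.random(n) < expit(eta)
        cols = MISSINGNESS_BLOCKS[block]()
        for c in cols:
            if df[c].dtype != object and df[c].dtype != float:
                df[c] = df[c].astype(float)
            df.loc[missing, c] = np.nan
        df[f"missing_{block}"] = missing
    return Cohort(participants=df, medications=cohort.medications.copy(),
                  config=cohort.config)
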