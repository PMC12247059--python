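"""Resource-use valuation under NHS+PSS and societal perspectives.

Costs are ``count x unit cost`` per category, with unit costs inflated to a
common reference price year (2021-22 style index).  The base-case (NHS and
personal social services) perspective covers primary/community care,
hospital care, NHS mental-health services, depression medications and social
care; the societal perspective additionally counts travel, productivity
losses, charity support (proxied at a paid home-care worker's hourly rate),
private mental healthcare and self-care.

Three valuation rules need care:

* medications: ``cost = daily_dose x days_taken x price per dose-unit-day``;
  a missing dose falls back to the formulary-recommended daily dose, and
  missing days fall back to the mean of the observed days for that drug
  (computed across the dataset before any substitution);
* charity support: hours x the home-care hourly rate;
* productivity loss: hours x (median weekly earnings / weekly hours).

Extreme observations (e.g. a multi-week in-patient stay) are costed as
recorded — no trimming or winsorising, since such events do occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import (
    CATEGORIES_6M_ONLY,
    CATEGORIES_BOTH,
    Cohort,
    DRUG_TYPICAL_DOSE_MG,
)

PERSPECTIVE_NHS_PSS = "nhs_pss"
PERSPECTIVE_SOCIETAL = "societal"

#: analysis-level cost groups and the unit categories they aggregate.
#: Groups (not individual visit types) are the unit of imputation.
COST_GROUPS = {
    "community": ["community_care"],
    "hospital": ["hospital_care"],
    "mental_health": ["mental_health"],
    "medication": [],  # valued from medication records, not counts
    "social": ["social_care"],
    "societal_other": [
        "travel", "productivity_hours", "charity_hours", "private_care",
        "self_care",
    ],
}
NHS_PSS_GROUPS = ["community", "hospital", "mental_health", "medication", "social"]
SOCIETAL_ONLY_GROUPS = ["societal_other"]


@dataclass
class UnitCostTable:
    """Per-category unit prices plus a price-year inflation index.

    ``table`` columns: category, unit_cost_gbp, price_year, perspective
    (``nhs_pss`` or ``societal_only``).  ``inflation_index`` maps price year
    to an index value; all costs are re-expressed at ``reference_year``.
    """

    table: pd.DataFrame
    inflation_index: dict = field(default_factory=lambda: {2022: 100.0})
    reference_year: int = 2022

    def __post_init__(self) -> None:
        req = ["category", "unit_cost_gbp", "price_year", "perspective"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"unit-cost table lacks columns {missing}")
        if (self.table["unit_cost_gbp"] < 0).any():
            raise ValueError("unit costs must be non-negative")
        for y in self.table["price_year"].unique():
            if int(y) not in self.inflation_index:
                raise ValueError(f"inflation index undefined for price year {y}")
        if self.reference_year not in self.inflation_index:
            raise ValueError("inflation index undefined for the reference year")
        self._rows = {
            r.category: (float(r.unit_cost_gbp), int(r.price_year), r.perspective)
            for r in self.table.itertuples()
        }

    @classmethod
    def from_csv(cls, path: str | Path, inflation_index=None,
                 reference_year: int = 2022) -> "UnitCostTable":
        return cls(pd.read_csv(path),
                   inflation_index=inflation_index or {reference_year: 100.0},
                   reference_year=reference_year)

    def unit_cost(self, category: str) -> float:
        """Unit cost at reference-year prices."""
        if category not in self._rows:
            raise KeyError(f"no unit cost for category {category!r}")
        cost, year, _ = self._rows[category]
        return inflate(cost, year, self)

    def perspective_of(self, category: str) -> str:
        if category not in self._rows:
            raise KeyError(f"no unit cost for category {category!r}")
        return self._rows[category][2]


def inflate(cost: float, price_year: int, table: UnitCostTable) -> float:
    """Re-express ``cost`` from ``price_year`` at the table's reference year."""
    idx = table.inflation_index
    if price_year not in idx:
        raise KeyError(f"price year {price_year} not in inflation index")
    return cost * idx[table.reference_year] / idx[price_year]


def cost_charity(hours: float, home_care_hourly_rate: float) -> float:
    """Value charity support at the paid home-care worker hourly rate."""
    if hours < 0:
        raise ValueError("charity hours must be non-negative")
    return hours * home_care_hourly_rate


def cost_productivity(hours_lost: float, median_weekly_earnings: float,
                      weekly_hours: float = 37.5) -> float:
    """Value lost work time at median earnings per working hour."""
    if weekly_hours <= 0:
        raise ValueError("weekly_hours must be positive")
    return hours_lost * median_weekly_earnings / weekly_hours


def cost_medications(medications: pd.DataFrame,
                     bnf_defaults: dict | None = None,
                     price_per_unit_day: dict | None = None) -> pd.Series:
    """Per-participant medication cost with formulary/mean fallbacks.

    ``medications`` is long format with columns ``id, drug, daily_dose_mg,
    days_taken``.  Cost per record = dose x days x price-per-dose-unit-day.
    Missing dose -> the formulary default for the drug; missing days -> the
    mean of observed days for that drug across the whole dataset (computed
    before substitution).  Raises on an unpriced drug, a missing dose with no
    formulary default, or a drug whose days are all missing.
    Returns a Series of GBP indexed by participant id (participants without
    records are absent; treat as zero).
    """
    bnf_defaults = DRUG_TYPICAL_DOSE_MG if bnf_defaults is None else bnf_defaults
    prices = DEFAULT_DRUG_PRICE_PER_MG_DAY if price_per_unit_day is None else price_per_unit_day
    if medications.empty:
        return pd.Series(dtype=float, name="medication_cost")
    med = medications.copy()
    unpriced = sorted(set(med["drug"]) - set(prices))
    if unpriced:
        raise KeyError(f"no price for drug(s) {unpriced}")
    observed_days = med.groupby("drug")["days_taken"].mean()

    def one(row):
        dose = row["daily_dose_mg"]
        if pd.isna(dose):
            if row["drug"] not in bnf_defaults:
                raise KeyError(f"missing dose and no formulary default for "
                               f"{row['drug']!r}")
            dose = bnf_defaults[row["drug"]]
        days = row["days_taken"]
        if pd.isna(days):
            days = observed_days.get(row["drug"], np.nan)
            if pd.isna(days):
                raise ValueError(
                    f"all days_taken missing for {row['drug']!r}; no mean available"
                )
        return dose * days * prices[row["drug"]]

    med["cost"] = med.apply(one, axis=1)
    out = med.groupby("id")["cost"].sum()
    out.name = "medication_cost"
    return out


@dataclass
class CostBreakdown:
    """Per-category costs (reference-year GBP) and the two perspective totals."""

    id: object
    components: dict
    total_nhs_pss: float
    total_societal: float


def total_costs(record_counts: dict, table: UnitCostTable,
                perspective: str = PERSPECTIVE_NHS_PSS,
                medication_cost: float = 0.0,
                record_id=None) -> CostBreakdown:
    """Cost one participant's resource-use counts.

    ``record_counts`` maps category -> count.  Societal-only categories are
    always costed and recorded in the components, but enter the headline
    total only under the societal perspective (the NHS+PSS total never
    includes them).  ``medication_cost`` is the precomputed output of
    :func:`cost_medications` for this participant.
    """
    if perspective not in (PERSPECTIVE_NHS_PSS, PERSPECTIVE_SOCIETAL):
        raise ValueError(f"unknown perspective {perspective!r}")
    components: dict = {}
    nhs = float(medication_cost)
    societal_extra = 0.0
    components["medication"] = float(medication_cost)
    for cat, count in record_counts.items():
        if count < 0:
            raise ValueError(f"negative count for {cat!r}")
        c = count * table.unit_cost(cat)
        components[cat] = c
        if table.perspective_of(cat) == "nhs_pss":
            nhs += c
        else:
            societal_extra += c
    return CostBreakdown(
        id=record_id,
        components=components,
        total_nhs_pss=nhs,
        total_societal=nhs + societal_extra,
    )


def cost_cohort(cohort: Cohort, table: UnitCostTable,
                timepoint: str) -> pd.DataFrame:
    """Grouped per-participant costs at one timepoint, NaN-propagating.

    Returns a DataFrame indexed like ``cohort.participants`` with one
    ``cost_<group>_<timepoint>`` column per applicable cost group.  A
    participant whose counts are missing at this timepoint gets NaN group
    costs (imputation happens downstream at this group level); the
    medication group is NaN when the participant's 6-month cost section is
    flagged missing.
    """
    df = cohort.participants
    suffix = "baseline" if timepoint == "baseline" else "6m"
    cats = list(CATEGORIES_BOTH) + (CATEGORIES_6M_ONLY if suffix == "6m" else [])
    out = pd.DataFrame(index=df.index)
    for group, members in COST_GROUPS.items():
        members = [m for m in members if m in cats]
        if group == "medication":
            if suffix != "6m":
                continue
            med = cost_medications(cohort.medications)
            col = df["id"].map(med).fillna(0.0)
            if "missing_costs_6m" in df.columns:
                col = col.mask(df["missing_costs_6m"].astype(bool))
            out[f"cost_{group}_{suffix}"] = col
            continue
        if not members:
            continue
        acc = pd.Series(0.0, index=df.index)
        for m in members:
            counts = df[f"{m}_{suffix}"]
            if (counts.dropna() < 0).any():
                raise ValueError(f"negative count in {m}_{suffix}")
            acc = acc + counts * table.unit_cost(m)
        out[f"cost_{group}_{suffix}"] = acc
    return out


def group_total(costs: pd.DataFrame, timepoint: str, perspective: str) -> pd.Series:
    """Sum grouped cost columns into the perspective's total at a timepoint."""
    suffix = "baseline" if timepoint == "baseline" else "6m"
    groups = list(NHS_PSS_GROUPS)
    if perspective == PERSPECTIVE_SOCIETAL:
        groups = groups + SOCIETAL_ONLY_GROUPS
    elif perspective != PERSPECTIVE_NHS_PSS:
        raise ValueError(f"unknown perspective {perspective!r}")
    cols = [f"cost_{g}_{suffix}" for g in groups if f"cost_{g}_{suffix}" in costs]
    return costs[cols].sum(axis=1, skipna=False)


# -- default valuation configuration (round-number fixture values) -----------

MEDIAN_WEEKLY_EARNINGS_GBP = 640.0
WEEKLY_WORK_HOURS = 37.5
HOME_CARE_HOURLY_RATE_GBP = 25.0

#: price per dose-unit (mg) per day, GBP
DEFAULT_DRUG_PRICE_PER_MG_DAY = {
    "citalopram": 0.005,
    "fluoxetine": 0.004,
    "sertraline": 0.002,
    "mirtazapine": 0.003,
}


def default_unit_cost_table() -> UnitCostTable:
    """Round-number unit costs at 2021-22 prices for the synthetic cohort.

    These are plausible orders of magnitude for UK tariffs (GP contact ~GBP
    40, in-patient night ~GBP 570, mental-health contact ~GBP 120), not any
    published schedule; real analyses supply their own CSV.
    """
    rows = [
        ("community_care", 40.0, 2022, "nhs_pss"),
        ("hospital_care", 570.0, 2022, "nhs_pss"),
        ("mental_health", 120.0, 2022, "nhs_pss"),
        ("social_care", 30.0, 2022, "nhs_pss"),
        ("travel", 5.0, 2022, "societal_only"),
        ("productivity_hours",
         cost_productivity(1.0, MEDIAN_WEEKLY_EARNINGS_GBP, WEEKLY_WORK_HOURS),
         2022, "societal_only"),
        ("charity_hours", cost_charity(1.0, HOME_CARE_HOURLY_RATE_GBP),
         2022, "societal_only"),
        ("private_care", 100.0, 2022, "societal_only"),
        ("self_care", 10.0, 2022, "societal_only"),
    ]
    return UnitCostTable(
        pd.DataFrame(rows, columns=["category", "unit_cost_gbp", "price_year",
                                    "perspective"]),
        inflation_index={2020: 96.0, 2021: 98.0, 2022: 100.0},
        reference_year=2022,
    )
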