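"""EQ-5D utility mapping and QALY computation over a 6-month horizon.

Five-level EQ-5D responses are mapped to three-level utilities via a
user-supplied lookup table keyed by the five domain levels plus age band and
sex (published crosswalk value sets are licensed, so the table contents are
configuration, not code).  Per-participant QALYs are the trapezoid (area
under the curve) between the baseline and 6-month utilities; no discounting
is applied over the half-year horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import UTILITY_CEIL, UTILITY_FLOOR

DOMAINS = ["mo", "sc", "ua", "pd", "ad"]  # mobility, self-care, usual
# activities, pain/discomfort, anxiety/depression
DAYS_PER_YEAR = 365.25


@dataclass
class UtilityMappingTable:
    """Lookup table (five 5L levels, age_band, sex) -> 3L utility index.

    ``table`` must have columns ``mo, sc, ua, pd, ad`` (integer levels 1-5),
    ``age_band``, ``sex`` and ``utility``.  Lookups are exact; a missing key
    raises ``KeyError`` naming the combination rather than silently
    defaulting.
    """

    table: pd.DataFrame
    name: str = "synthetic"
    version: str = "0"

    def __post_init__(self) -> None:
        required = DOMAINS + ["age_band", "sex", "utility"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"mapping table lacks columns {missing}")
        bad = self.table[
            (self.table["utility"] < UTILITY_FLOOR)
            | (self.table["utility"] > UTILITY_CEIL)
        ]
        if len(bad):
            raise ValueError("mapping table utilities outside the 3L value-set range")
        self._index = {
            (int(r.mo), int(r.sc), int(r.ua), int(r.pd), int(r.ad),
             r.age_band, r.sex): float(r.utility)
            for r in self.table.itertuples()
        }

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "UtilityMappingTable":
        return cls(pd.read_csv(path), **kw)

    def lookup(self, levels, age_band, sex) -> float:
        levels = tuple(int(x) for x in levels)
        if len(levels) != 5 or any(not 1 <= x <= 5 for x in levels):
            raise ValueError("responses must be five levels, each in 1-5")
        key = levels + (age_band, sex)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(
                f"no utility for responses {levels}, age_band={age_band!r}, "
                f"sex={sex!r} in value set {self.name!r}"
            ) from None


def map_utility(responses, age_band, sex, table: UtilityMappingTable) -> float:
    """Pure table lookup of the utility for one response profile."""
    return table.lookup(responses, age_band, sex)


def qaly_auc(utility_baseline, utility_6m, horizon_years: float = 0.5):
    """Trapezoid QALY between the two assessments: 0.5*(u0+u6)*horizon.

    Accepts scalars or arrays; missing utilities are an error here because
    imputation happens upstream of QALY computation.
    """
    u0 = np.asarray(utility_baseline, dtype=float)
    u6 = np.asarray(utility_6m, dtype=float)
    if np.isnan(u0).any() or np.isnan(u6).any():
        raise ValueError("missing utility: impute before computing QALYs")
    for u in (u0, u6):
        if (u < UTILITY_FLOOR).any() or (u > UTILITY_CEIL).any():
            raise ValueError("utility outside [-0.594, 1]")
    q = 0.5 * (u0 + u6) * horizon_years
    return float(q) if q.ndim == 0 else q


def qaly_to_perfect_health_days(delta_qaly: float) -> float:
    """Express a QALY difference as equivalent days of perfect health.

    Sign-preserving, reported to 2 decimal places: -0.006 QALY is -2.19 days.
    """
    return round(float(delta_qaly) * DAYS_PER_YEAR, 2)


def synthetic_mapping_table(utility_full_health: float = 1.0) -> UtilityMappingTable:
    """Small synthetic value set for tests and examples (not a published set).

    Anchors the all-ones profile at ``utility_full_health`` and decrements
    utility linearly in the summed levels, with a small age-band/sex offset
    so that keying on age and sex is observable.
    """
    rows = []
    for age_band in ["65-74", "75+"]:
        for sex in ["female", "male"]:
            offset = (0.01 if age_band == "75+" else 0.0) + (
                0.005 if sex == "male" else 0.0
            )
            for mo in range(1, 6):
                for ad in range(1, 6):
                    # coarse grid: vary two domains, fix the rest at level 1
                    s = mo + ad - 2
                    rows.append(
                        dict(mo=mo, sc=1, ua=1, pd=1, ad=ad, age_band=age_band,
                             sex=sex,
                             utility=max(UTILITY_FLOOR,
                                         utility_full_health - 0.08 * s - offset
                                         if s else utility_full_health))
                    )
    return UtilityMappingTable(pd.DataFrame(rows), name="synthetic", version="1")
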