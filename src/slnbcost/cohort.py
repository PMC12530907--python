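"""Synthetic institutional cohorts.

The three treatment groups the cost parameters come from — SLNB, transoral
resection with simultaneous selective neck dissection (upfront SND), and
delayed isolated SND — are emulated as patient-level records: the raw
institutional data are not public, only their summary statistics.  Costs
follow the cohort cost distribution (truncated normal by default); length of
stay and 60-day visit counts follow Poisson laws centred so their medians
match the printed medians (1 vs 3 days, 2 vs 8 visits); theatre minutes
follow a truncated normal centred at the printed medians (92 vs 177).
Cost and utilization are drawn independently by default; an optional rank
correlation couples them for sensitivity testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costing import CostDistribution

__all__ = [
    "COHORTS",
    "CohortSpec",
    "PatientRecord",
    "CohortSummary",
    "TABLE_COHORT_SPECS",
    "generate_cohort",
    "summarize_cohort",
    "pair_cohorts",
    "records_to_frame",
    "frame_to_records",
]

COHORTS = ("slnb", "upfront_snd", "delayed_snd")


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for one synthetic cohort."""

    cohort: str
    n: int
    cost_mean: float
    cost_sd: float
    los_median: int
    theatre_median: float
    visits_median: int
    cT1_fraction: float
    female_fraction: float = 0.5
    age_mean: float = 54.0
    age_sd: float = 8.0
    cost_family: str = "truncated-normal"
    theatre_cv: float = 0.15          # SD of theatre minutes as fraction of median
    cost_utilization_corr: float = 0.0  # optional rank correlation, off by default

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if self.cost_sd < 0 or self.cost_mean <= 0:
            raise ValueError("cost_mean must be > 0 and cost_sd >= 0")
        for name in ("cT1_fraction", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.cost_utilization_corr <= 1.0:
            raise ValueError("cost_utilization_corr must be in [-1, 1]")

    @property
    def cost_distribution(self) -> CostDistribution:
        return CostDistribution(self.cost_mean, self.cost_sd, family=self.cost_family)


#: Default specs reproducing the institutional summary: cohort sizes 12/36/36,
#: cost mean/SD per group, and the printed utilization medians.
TABLE_COHORT_SPECS: dict[str, CohortSpec] = {
    "slnb": CohortSpec(
        cohort="slnb", n=12, cost_mean=5782.49, cost_sd=1767.17,
        los_median=1, theatre_median=92.0, visits_median=2,
        cT1_fraction=8 / 12, female_fraction=6 / 12, age_mean=53.2, age_sd=10.5,
    ),
    "upfront_snd": CohortSpec(
        cohort="upfront_snd", n=36, cost_mean=11117.25, cost_sd=2033.14,
        los_median=3, theatre_median=177.0, visits_median=8,
        cT1_fraction=19 / 36, female_fraction=20 / 36, age_mean=54.1, age_sd=6.7,
    ),
    "delayed_snd": CohortSpec(
        cohort="delayed_snd", n=36, cost_mean=7620.43, cost_sd=1750.17,
        los_median=3, theatre_median=177.0, visits_median=8,
        cT1_fraction=15 / 36, female_fraction=19 / 36, age_mean=54.2, age_sd=8.0,
    ),
}


@dataclass(frozen=True)
class PatientRecord:
    patient_id: int
    cohort: str
    age: float
    gender: str          # "female" | "male"
    cT: int              # 1 | 2
    total_cost: float
    length_of_stay: int
    theatre_minutes: float
    visits_60d: int
    comorbidities: Optional[str] = None  # matching hook, unused by default

    def __post_init__(self) -> None:
        if self.total_cost < 0:
            raise ValueError("total_cost must be >= 0")
        if self.length_of_stay < 0:
            raise ValueError("length_of_stay must be >= 0")
        if not self.theatre_minutes > 0:
            raise ValueError("theatre_minutes must be > 0")
        if self.visits_60d < 0:
            raise ValueError("visits_60d must be >= 0")


@dataclass(frozen=True)
class CohortSummary:
    """Summary statistics in the conventions of the source tables: mean/SD
    for costs, medians for utilization.  Moments that are undefined for the
    sample size are ``None`` rather than silently zero."""

    n: int
    cost_mean: Optional[float]
    cost_sd: Optional[float]
    los_median: Optional[float]
    theatre_median: Optional[float]
    visits_median: Optional[float]
    cT1_fraction: Optional[float]


def generate_cohort(spec: CohortSpec, n: Optional[int] = None,
                    seed: int | np.random.SeedSequence = 0) -> list[PatientRecord]:
    """Generate ``n`` synthetic patients (default ``spec.n``), deterministically
    for a given seed."""
    if n is None:
        n = spec.n
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)

    costs = spec.cost_distribution.sample(n, rng)
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 99.0)
    female = rng.random(n) < spec.female_fraction
    ct1 = rng.random(n) < spec.cT1_fraction

    # Poisson(lambda = printed median) has its median at the printed value
    # for the medians used here (1, 2, 3, 8).
    los = rng.poisson(spec.los_median, n)
    visits = rng.poisson(spec.visits_median, n)
    theatre_sd = spec.theatre_cv * spec.theatre_median
    a = (1.0 - spec.theatre_median) / theatre_sd
    theatre = stats.truncnorm.rvs(
        a, np.inf, loc=spec.theatre_median, scale=theatre_sd, size=n, random_state=rng
    )

    if spec.cost_utilization_corr != 0.0:
        # Rank-couple utilization to cost: reorder utilization draws so their
        # ranks follow a Gaussian-copula mix of the cost ranks.
        r = spec.cost_utilization_corr
        z_cost = stats.norm.ppf((stats.rankdata(costs) - 0.5) / n)
        z = r * z_cost + math.sqrt(1 - r * r) * rng.standard_normal(n)
        order = np.argsort(np.argsort(z))
        los = np.sort(los)[order]
        visits = np.sort(visits)[order]
        theatre = np.sort(theatre)[order]

    return [
        PatientRecord(
            patient_id=i,
            cohort=spec.cohort,
            age=float(age[i]),
            gender="female" if female[i] else "male",
            cT=1 if ct1[i] else 2,
            total_cost=float(costs[i]),
            length_of_stay=int(los[i]),
            theatre_minutes=float(theatre[i]),
            visits_60d=int(visits[i]),
        )
        for i in range(n)
    ]


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Mean/SD (n-1 denominator) and medians of a cohort; undefined moments
    (mean at n=0, SD at n<2) are reported as ``None``."""
    n = len(records)
    if n == 0:
        return CohortSummary(0, None, None, None, None, None, None)
    costs = np.array([r.total_cost for r in records])
    sd = float(np.std(costs, ddof=1)) if n >= 2 else None
    return CohortSummary(
        n=n,
        cost_mean=float(costs.mean()),
        cost_sd=sd,
        los_median=float(np.median([r.length_of_stay for r in records])),
        theatre_median=float(np.median([r.theatre_minutes for r in records])),
        visits_median=float(np.median([r.visits_60d for r in records])),
        cT1_fraction=float(np.mean([r.cT == 1 for r in records])),
    )


class MatchingError(ValueError):
    """Raised when 1:k matching is infeasible; carries the unmatched strata."""

    def __init__(self, unmatched: list[tuple[str, int]]):
        self.unmatched = unmatched
        strata = ", ".join(f"(gender={g}, cT={t})" for g, t in unmatched)
        super().__init__(f"matching infeasible; short strata: {strata}")


def pair_cohorts(
    slnb_records: Sequence[PatientRecord],
    comparison_records: Sequence[PatientRecord],
    ratio: int = 3,
) -> dict[int, list[int]]:
    """Match each SLNB patient to ``ratio`` distinct comparators with exact
    gender and cT match and nearest age (ties: lowest patient_id).

    Comparators are never reused.  Returns ``{slnb_id: [comparator_ids]}``;
    raises :class:`MatchingError` listing short strata when infeasible.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    # Feasibility per (gender, cT) stratum first, so the error is complete.
    need: dict[tuple[str, int], int] = {}
    for r in slnb_records:
        key = (r.gender, r.cT)
        need[key] = need.get(key, 0) + ratio
    have: dict[tuple[str, int], int] = {}
    for r in comparison_records:
        key = (r.gender, r.cT)
        have[key] = have.get(key, 0) + 1
    short = sorted(k for k, v in need.items() if have.get(k, 0) < v)
    if short:
        raise MatchingError(short)

    pool = {r.patient_id: r for r in comparison_records}
    matches: dict[int, list[int]] = {}
    for rec in sorted(slnb_records, key=lambda r: r.patient_id):
        eligible = [
            c for c in pool.values() if c.gender == rec.gender and c.cT == rec.cT
        ]
        eligible.sort(key=lambda c: (abs(c.age - rec.age), c.patient_id))
        chosen = eligible[:ratio]
        if len(chosen) < ratio:  # pool exhausted by earlier matches
            raise MatchingError([(rec.gender, rec.cT)])
        matches[rec.patient_id] = [c.patient_id for c in chosen]
        for c in chosen:
            del pool[c.patient_id]
    return matches


_COLUMNS = [
    "patient_id", "cohort", "age", "gender", "cT",
    "total_cost", "length_of_stay", "theatre_minutes", "visits_60d",
]


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per patient, fixed column order (CSV-ready)."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in _COLUMNS} for r in records], columns=_COLUMNS
    )


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    return [
        PatientRecord(
            patient_id=int(row.patient_id),
            cohort=str(row.cohort),
            age=float(row.age),
            gender=str(row.gender),
            cT=int(row.cT),
            total_cost=float(row.total_cost),
            length_of_stay=int(row.length_of_stay),
            theatre_minutes=float(row.theatre_minutes),
            visits_60d=int(row.visits_60d),
        )
        for row in frame.itertuples(index=False)
    ]
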