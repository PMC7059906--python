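"""Excess LYL entirely from aggregated (tabular) data.

When neither the diseased group nor the reference is available at the
individual level, LYL can still be estimated from age-specific mortality
rates (or survivor proportions) plus the number of new cases at each
age.  Both sides are treated as piecewise-exponential survival curves;
the landmark construction is implicit in the diseased table, whose rates
are understood as conditional-on-onset mortality from each age onward.
No bootstrap is offered here: there is no individual resampling unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .lifetable import LifeTable, lifetable_to_curve

__all__ = [
    "AggregatedCohort",
    "AggregatedLYL",
    "lyl_aggregated",
    "lyl_aggregated_range",
    "tabulate_rates",
]


@dataclass
class AggregatedCohort:
    """Diseased population summarized as per-age rates and new-case counts."""

    table: LifeTable
    new_cases: np.ndarray

    def __post_init__(self) -> None:
        self.new_cases = np.asarray(self.new_cases, dtype=float)
        if self.new_cases.shape != self.table.ages.shape:
            raise ValueError("new_cases must have one value per age")
        if np.any(self.new_cases < 0):
            raise ValueError("new_cases must be non-negative")
        if self.new_cases.sum() <= 0:
            raise ValueError("total new cases must be positive")

    @property
    def ages(self) -> np.ndarray:
        return self.table.ages


@dataclass
class AggregatedLYL:
    """Paired diseased/reference report from aggregated inputs."""

    condition_age: float
    tau: float
    diseased_le: float
    reference_le: float

    @property
    def diseased_lyl(self) -> float:
        return (self.tau - self.condition_age) - self.diseased_le

    @property
    def reference_lyl(self) -> float:
        return (self.tau - self.condition_age) - self.reference_le

    @property
    def excess(self) -> float:
        return self.diseased_lyl - self.reference_lyl

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": ["life_expectancy", "lyl_total"],
                "diseased": [self.diseased_le, self.diseased_lyl],
                "reference": [self.reference_le, self.reference_lyl],
                "difference": [self.diseased_le - self.reference_le, self.excess],
            }
        ).set_index("quantity")


def lyl_aggregated(
    agg: AggregatedCohort, ref: LifeTable, age_specific: float, tau: float
) -> AggregatedLYL:
    """Excess LYL at one conditioning age from aggregated data.

    Both tables must span ``[age_specific, tau]``; with administrative
    data ending at some age, tau has to be capped there.
    """
    d_curve = lifetable_to_curve(agg.table, age_specific, tau)
    r_curve = lifetable_to_curve(ref, age_specific, tau)
    return AggregatedLYL(
        condition_age=float(age_specific),
        tau=float(tau),
        diseased_le=d_curve.restricted_area(age_specific, tau),
        reference_le=r_curve.restricted_area(age_specific, tau),
    )


def lyl_aggregated_range(
    agg: AggregatedCohort, ref: LifeTable, age_begin: int, age_end: int, tau: float
) -> tuple[pd.DataFrame, AggregatedLYL]:
    """Per-age excess LYL plus the new-case-weighted overall summary.

    Returns the per-age frame (ages, cases, both LEs/LYLs, excess) and an
    :class:`AggregatedLYL` whose quantities are weighted means over the
    age-at-onset distribution (``condition_age`` is the weighted mean
    onset age).
    """
    a0, a1 = int(age_begin), int(age_end)
    if a1 < a0:
        raise ValueError("age_end must be >= age_begin")
    if a1 >= tau:
        raise ValueError("age_end must be below tau")
    sel = (agg.ages >= a0) & (agg.ages <= a1)
    ages = agg.ages[sel].astype(float)
    cases = agg.new_cases[sel]
    if ages.size == 0 or cases.sum() <= 0:
        raise ValueError("no new cases in the requested age range")

    rows = [lyl_aggregated(agg, ref, a, tau) for a in ages]
    frame = pd.DataFrame(
        {
            "age": ages.astype(int),
            "new_cases": cases,
            "diseased_le": [r.diseased_le for r in rows],
            "diseased_lyl": [r.diseased_lyl for r in rows],
            "reference_le": [r.reference_le for r in rows],
            "reference_lyl": [r.reference_lyl for r in rows],
            "excess": [r.excess for r in rows],
        }
    )
    w = cases / cases.sum()
    summary = AggregatedLYL(
        condition_age=float(np.dot(w, ages)),
        tau=float(tau),
        diseased_le=float(np.dot(w, frame["diseased_le"])),
        reference_le=float(np.dot(w, frame["reference_le"])),
    )
    return frame, summary


def tabulate_rates(cohort: Cohort, age_begin: int, age_end: int) -> pd.DataFrame:
    """Yearly person-years, deaths and mortality rates of a cohort.

    Left-truncation aware: a person contributes person-time in
    ``[x, x+1)`` only between their entry and exit ages.  This is the
    bridge from individual-level data to the aggregated mode (and the
    basis of its consistency check).
    """
    ages = np.arange(int(age_begin), int(age_end) + 1)
    lo = ages[:, None].astype(float)
    hi = lo + 1.0
    py = np.clip(np.minimum(cohort.exit, hi) - np.maximum(cohort.entry, lo), 0.0, None).sum(axis=1)
    death_age = cohort.exit[cohort.cause_index >= 0]
    deaths = np.array([np.sum((death_age >= a) & (death_age < a + 1)) for a in ages], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(py > 0, deaths / np.where(py > 0, py, 1.0), 0.0)
    out = pd.DataFrame({"age": ages, "person_years": py, "deaths": deaths, "rate": rate})
    if cohort.onset is not None:
        onsets = cohort.onset[np.isfinite(cohort.onset)]
        binned = np.floor(onsets).astype(int)
        out["new_cases"] = [int(np.sum(binned == a)) for a in ages]
    return out
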