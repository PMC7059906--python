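"""Life Years Lost over a range of conditioning ages, with onset weights.

A disease with variable age at onset has one LYL estimate per onset age;
the overall burden is the average of those estimates weighted by the
number of new cases at each age.  ``lyl_over_range`` builds the per-age
table (one row per integer age) and ``weighted_summary`` collapses it
using :class:`AgeWeights` built from observed onset ages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .point import LYLEstimate, lyl_at_age

__all__ = ["LYLTable", "AgeWeights", "lyl_over_range", "weights_from_onsets", "weighted_summary"]


@dataclass
class AgeWeights:
    """New-case counts per integer age (the n_i of the weighted summary)."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        self.counts = {int(a): int(c) for a, c in self.counts.items()}
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("weights must be non-negative")
        if sum(self.counts.values()) <= 0:
            raise ValueError("total weight must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LYLTable:
    """Per-integer-age LYL estimates sharing one restriction age tau.

    ``rows[i]`` is ``None`` for ages where nobody was at risk (flagged
    missing rather than interpolated).
    """

    tau: float
    ages: np.ndarray
    rows: list[LYLEstimate | None]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("table ages must be consecutive integers")
        if len(self.rows) != self.ages.size:
            raise ValueError("one row per age required")
        for r in self.rows:
            if r is not None and r.tau != self.tau:
                raise ValueError("all rows must share tau")

    def row_at(self, age: int) -> LYLEstimate | None:
        i = int(age) - int(self.ages[0])
        if i < 0 or i >= self.ages.size:
            raise KeyError(f"age {age} outside table range")
        return self.rows[i]

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: age, n at risk, restricted LE, total and per-cause LYL."""
        causes: list[str] = []
        for r in self.rows:
            if r is not None:
                causes = list(r.lyl_by_cause)
                break
        recs = []
        for age, r in zip(self.ages, self.rows):
            if r is None:
                recs.append({"age": age, "n_at_risk": 0, "missing": True})
            else:
                rec = {
                    "age": age,
                    "n_at_risk": r.n_at_risk,
                    "missing": False,
                    "life_expectancy": r.restricted_life_expectancy,
                    "lyl_total": r.lyl_total,
                }
                for c in causes:
                    rec[f"lyl_{c}"] = r.lyl_by_cause[c]
                recs.append(rec)
        return pd.DataFrame(recs)


def lyl_over_range(cohort: Cohort, age_begin: int, age_end: int, tau: float) -> LYLTable:
    """One ``lyl_at_age`` per integer age in ``[age_begin, age_end]``.

    Ages with an empty risk set produce a flagged missing row instead of
    failing the whole range.
    """
    a0, a1 = int(age_begin), int(age_end)
    if a1 < a0:
        raise ValueError("age_end must be >= age_begin")
    if a1 >= tau:
        raise ValueError("age_end must be below tau")
    ages = np.arange(a0, a1 + 1)
    rows: list[LYLEstimate | None] = []
    for a in ages:
        try:
            rows.append(lyl_at_age(cohort, float(a), float(tau)))
        except ValueError as err:
            if "at risk" in str(err):
                rows.append(None)
            else:
                raise
    return LYLTable(tau=float(tau), ages=ages, rows=rows)


def weights_from_onsets(onset_ages, age_begin: int, age_end: int) -> AgeWeights:
    """Bin observed onset ages into integer-age case counts.

    Binning is by floor: an onset at 45.9 years counts at age 45.  Onsets
    outside ``[age_begin, age_end + 1)`` are an error (listed), because
    they would silently drop weight from the summary.
    """
    onsets = np.asarray(onset_ages, dtype=float)
    onsets = onsets[np.isfinite(onsets)]
    if onsets.size == 0:
        raise ValueError("no onset ages provided")
    binned = np.floor(onsets).astype(int)
    bad = onsets[(binned < int(age_begin)) | (binned > int(age_end))]
    if bad.size:
        raise ValueError(
            f"onset ages outside [{age_begin}, {age_end + 1}): {np.sort(bad)[:10].tolist()}"
        )
    ages, counts = np.unique(binned, return_counts=True)
    return AgeWeights({int(a): int(c) for a, c in zip(ages, counts)})


def weighted_summary(table: LYLTable, weights: AgeWeights) -> LYLEstimate:
    """Case-weighted averages of every column of the per-age table.

    Each quantity is ``sum_i n_i x_i / sum_i n_i`` over ages with
    positive weight.  The returned estimate's ``condition_age`` is the
    case-weighted mean age, so the conservation identity
    ``LE + LYL = tau - mean_age`` carries over to the summary.
    """
    w_ages = [a for a, c in weights.counts.items() if c > 0]
    missing = [a for a in w_ages if table.row_at(a) is None]
    if missing:
        raise ValueError(f"positive weight on missing table row(s): {missing}")
    n = np.array([weights.counts[a] for a in w_ages], dtype=float)
    rows = [table.row_at(a) for a in w_ages]
    total_w = n.sum()

    causes = list(rows[0].lyl_by_cause)
    le = float(np.dot(n, [r.restricted_life_expectancy for r in rows]) / total_w)
    mean_age = float(np.dot(n, w_ages) / total_w)
    by_cause = {
        c: float(np.dot(n, [r.lyl_by_cause[c] for r in rows]) / total_w) for c in causes
    }
    lyl_total = float(np.dot(n, [r.lyl_total for r in rows]) / total_w)
    return LYLEstimate(
        condition_age=mean_age,
        tau=table.tau,
        restricted_life_expectancy=le,
        lyl_total=lyl_total,
        lyl_by_cause=by_cause,
        n_at_risk=int(total_w),
    )
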