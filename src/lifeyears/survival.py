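"""Conditional survival and cause-specific cumulative incidence estimation.

The estimators here are the nonparametric building blocks of the Life
Years Lost method: a product-limit (Kaplan-Meier) survivor curve with
delayed entry, conditioned on being at risk at a landmark age, and the
Aalen-Johansen cause-specific cumulative incidence functions (CIFs) that
partition total mortality into competing causes.

Conventions
-----------
* Curves are right-continuous step functions; integration uses the value
  on ``[t_j, t_{j+1})``.
* The risk set at an event age ``t`` contains every person with
  ``max(entry, a) < t <= exit`` where ``a`` is the landmark
  (conditioning) age.  Persons entering after the landmark join the risk
  set at their entry age (standard delayed-entry behaviour).
* Ties: all events at one age are processed jointly against the risk set
  just before that age; censorings tied with deaths stay in the risk set
  for those deaths.
* The survivor curve is reported as ``1 - sum_k F_k`` so that the
  Aalen-Johansen additivity ``S(t) + sum_k F_k(t) = 1`` holds exactly at
  every jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "StepCurve",
    "CompetingRisksCurves",
    "fit_conditional_survival",
    "fit_competing_risks",
    "restricted_area",
    "numbers_at_risk",
]


@dataclass
class StepCurve:
    """Right-continuous step function on ``[start_age, inf)``.

    ``values[j]`` is the function value on ``[jump_ages[j], jump_ages[j+1])``;
    before the first jump the value is ``initial`` (1 for a survivor
    curve, 0 for a CIF).  After the last jump the curve stays flat, which
    matches the usual Kaplan-Meier extension up to the administrative
    censoring age.
    """

    start_age: float
    jump_ages: np.ndarray
    values: np.ndarray
    initial: float = 1.0

    def __post_init__(self) -> None:
        self.jump_ages = np.asarray(self.jump_ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.jump_ages.shape != self.values.shape:
            raise ValueError("jump_ages and values must have equal length")
        if self.jump_ages.size:
            if np.any(np.diff(self.jump_ages) <= 0):
                raise ValueError("jump ages must be strictly increasing")
            if self.jump_ages[0] <= self.start_age:
                raise ValueError("jump ages must lie after start_age")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("curve values must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    def value_at(self, t) -> np.ndarray | float:
        """Evaluate the step function (right-continuous) at age(s) ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_ages, t, side="right") - 1
        vals = np.concatenate(([self.initial], self.values))
        out = vals[idx + 1]
        return out if out.ndim else float(out)

    def restricted_area(self, from_age: float, to_age: float) -> float:
        return restricted_area(self, from_age, to_age)


@dataclass
class CompetingRisksCurves:
    """Survivor curve plus one CIF per cause, on a shared jump grid."""

    survival: StepCurve
    cifs: dict[str, StepCurve]
    condition_age: float
    n_at_risk: int = field(default=0)

    def __post_init__(self) -> None:
        grids = [self.survival.jump_ages] + [c.jump_ages for c in self.cifs.values()]
        for g in grids[1:]:
            if g.shape != grids[0].shape or (g.size and not np.array_equal(g, grids[0])):
                raise ValueError("all curves must share one jump-age grid")


# ----------------------------------------------------------------------
# core estimator (array-level, reused by the bootstrap hot loop)
# ----------------------------------------------------------------------

def _fit_arrays(
    entry: np.ndarray,
    exit_: np.ndarray,
    cause_index: np.ndarray,
    n_causes: int,
    condition_age: float,
):
    """Aalen-Johansen fit conditioned on being at risk at ``condition_age``.

    Returns ``(event_ages, survival, cif_matrix, n_at_landmark)`` where
    ``cif_matrix`` has one column per cause.  Raises ``ValueError`` when
    nobody is ever at risk past the landmark.
    """
    a = float(condition_age)
    keep = exit_ > a
    if not keep.any():
        raise ValueError(f"no individuals at risk at age {a:g}")
    e = np.maximum(entry[keep], a)
    x = exit_[keep]
    c = cause_index[keep]
    n_at_landmark = int(np.sum(entry <= a) - np.sum(exit_ <= a))

    death = c >= 0
    times = np.unique(x[death])
    if times.size == 0:  # everyone censored: flat curve, no jumps
        empty = np.empty(0)
        return empty, empty.copy(), np.empty((0, n_causes)), n_at_landmark

    # risk set just before each event age: #{e < t <= x}
    xs = np.sort(x)
    es = np.sort(e)
    m = x.size
    n_risk = (m - np.searchsorted(xs, times, side="left")).astype(float) - (
        m - np.searchsorted(es, times, side="left")
    )

    d = np.zeros((times.size, n_causes))
    ti = np.searchsorted(times, x[death])
    np.add.at(d, (ti, c[death]), 1.0)
    d_tot = d.sum(axis=1)

    # S(t-) from the product-limit recursion, then per-cause increments
    surv_prev = np.concatenate(([1.0], np.cumprod(1.0 - d_tot / n_risk)[:-1]))
    inc = surv_prev[:, None] * d / n_risk[:, None]
    cif = np.cumsum(inc, axis=0)
    surv = 1.0 - cif.sum(axis=1)
    np.clip(surv, 0.0, None, out=surv)
    return times, surv, cif, n_at_landmark


def fit_competing_risks(cohort: Cohort, condition_age: float) -> CompetingRisksCurves:
    """Fit the conditional survivor curve and per-cause CIFs at a landmark age.

    The estimate uses all persons at risk after ``condition_age``:
    those under observation at the landmark plus any delayed entrants
    whose entry age exceeds it.

    Raises
    ------
    ValueError
        If no person is at risk at or after ``condition_age``.
    """
    times, surv, cif, n_lm = _fit_arrays(
        cohort.entry, cohort.exit, cohort.cause_index, len(cohort.cause_labels), condition_age
    )
    survival = StepCurve(condition_age, times, surv, initial=1.0)
    cifs = {
        label: StepCurve(condition_age, times, cif[:, i], initial=0.0)
        for i, label in enumerate(cohort.cause_labels)
    }
    return CompetingRisksCurves(survival, cifs, float(condition_age), n_at_risk=n_lm)


def fit_conditional_survival(cohort: Cohort, condition_age: float) -> StepCurve:
    """Product-limit survivor curve conditional on being alive at ``condition_age``."""
    return fit_competing_risks(cohort, condition_age).survival


# ----------------------------------------------------------------------

def restricted_area(curve: StepCurve, from_age: float, to_age: float) -> float:
    """Exact area under a right-continuous step function on ``[from_age, to_age]``.

    This is the tau-restricted mean when applied to a survivor curve with
    ``from_age`` the conditioning age and ``to_age`` = tau.
    """
    if to_age <= from_age:
        raise ValueError("to_age must exceed from_age")
    if from_age < curve.start_age - 1e-12:
        raise ValueError("from_age lies before the curve's start age")
    breaks = np.concatenate(([curve.start_age], curve.jump_ages, [np.inf]))
    vals = np.concatenate(([curve.initial], curve.values))
    lo = np.maximum(breaks[:-1], from_age)
    hi = np.minimum(breaks[1:], to_age)
    widths = np.clip(hi - lo, 0.0, None)
    return float(np.dot(vals, widths))


def numbers_at_risk(cohort: Cohort, ages) -> pd.DataFrame:
    """Risk-set sizes and cumulative event counts at the requested ages.

    A person is at risk at age ``a`` when ``entry <= a < exit``.  Used by
    the sufficiency diagnostic: sparse risk sets (especially at old ages)
    make the nonparametric estimates unreliable.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if ages.size == 0:
        raise ValueError("ages must be non-empty")
    at_risk = [int(np.sum((cohort.entry <= a) & (a < cohort.exit))) for a in ages]
    deaths = cohort.exit[cohort.cause_index >= 0]
    events = [int(np.sum(deaths <= a)) for a in ages]
    return pd.DataFrame({"age": ages, "n_at_risk": at_risk, "n_events_so_far": events})
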