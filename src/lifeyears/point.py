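"""Life Years Lost at one conditioning age.

For persons alive (and, for a diseased cohort, already diagnosed or
entering later) at age ``a``, the tau-restricted remaining life
expectancy is the area under the conditional survivor curve from ``a``
to ``tau``; the Life Years Lost before ``tau`` is the complementary area
``(tau - a) - LE``, and the Aalen-Johansen CIF areas split that loss by
cause of death.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .survival import CompetingRisksCurves, fit_competing_risks, restricted_area

__all__ = ["LYLEstimate", "lyl_at_age", "stacked_series"]


@dataclass
class LYLEstimate:
    """Restricted life expectancy and cause-decomposed life lost at one age.

    ``restricted_life_expectancy + lyl_total == tau - condition_age`` by
    construction, and the per-cause losses sum to ``lyl_total`` (up to
    float round-off).
    """

    condition_age: float
    tau: float
    restricted_life_expectancy: float
    lyl_total: float
    lyl_by_cause: dict[str, float]
    n_at_risk: int
    curves: CompetingRisksCurves | None = field(default=None, repr=False, compare=False)

    def quantities(self) -> dict[str, float]:
        """Flat name -> value mapping (used by bootstrap and comparisons)."""
        out = {
            "life_expectancy": self.restricted_life_expectancy,
            "lyl_total": self.lyl_total,
        }
        for cause, v in self.lyl_by_cause.items():
            out[f"lyl_{cause}"] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        q = self.quantities()
        return pd.DataFrame(
            {"quantity": list(q), "years": list(q.values())}
        )


def lyl_at_age(cohort: Cohort, condition_age: float, tau: float) -> LYLEstimate:
    """Estimate Life Years Lost between ``condition_age`` and ``tau``.

    Parameters
    ----------
    cohort : Cohort
        Individual-level data; for a diseased population, entry should be
        the onset age (see :meth:`Cohort.diseased`).
    condition_age : float
        Landmark age ``a``: estimation conditions on being at risk here.
    tau : float
        Restriction age; losses are interpreted as life lost before
        ``tau`` (typically the administrative censoring age).

    Raises
    ------
    ValueError
        If ``condition_age >= tau`` or no one is at risk at the landmark.
    """
    a, t = float(condition_age), float(tau)
    if a >= t:
        raise ValueError("condition_age must be strictly below tau")
    curves = fit_competing_risks(cohort, a)
    le = restricted_area(curves.survival, a, t)
    lyl_by_cause = {
        cause: restricted_area(cif, a, t) for cause, cif in curves.cifs.items()
    }
    return LYLEstimate(
        condition_age=a,
        tau=t,
        restricted_life_expectancy=le,
        lyl_total=(t - a) - le,
        lyl_by_cause=lyl_by_cause,
        n_at_risk=curves.n_at_risk,
        curves=curves,
    )


def stacked_series(curves: CompetingRisksCurves, tau: float) -> pd.DataFrame:
    """Plot data for the stacked-CIF display on ``[a, tau]``.

    Columns: ``age``, ``survival``, then one cumulative column per cause
    (``survival + F_1``, ``survival + F_1 + F_2`` ...).  The topmost
    series is identically 1, so the bands partition the unit strip into
    an "alive" region (area = restricted LE) and per-cause "dead" regions
    (areas = cause-specific LYL).
    """
    a = curves.condition_age
    jumps = curves.survival.jump_ages
    ages = np.concatenate(([a], jumps[jumps <= tau], [tau]))
    ages = np.unique(ages)
    out = pd.DataFrame({"age": ages})
    level = np.asarray(curves.survival.value_at(ages), dtype=float)
    out["survival"] = level
    for cause, cif in curves.cifs.items():
        level = level + np.asarray(cif.value_at(ages), dtype=float)
        out[f"survival+{cause}"] = level
    return out
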