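"""Excess Life Years Lost: diseased cohort versus a reference population.

The reference can be a second individual-level fit (same estimator run
on the general population) or a standard life table.  A side supplied
without bootstrap replicates is treated as estimated without
uncertainty, which is reasonable when it comes from a whole-population
register or a national life table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import _QUANTILE_METHOD, BootstrapResult
from .lifetable import LifeTable, lifetable_to_curve
from .point import LYLEstimate
from .ranges import AgeWeights, LYLTable, weighted_summary

__all__ = ["ExcessLYL", "excess_lyl", "excess_lyl_vs_lifetable"]


@dataclass
class ExcessLYL:
    """Per-quantity diseased/reference values and their difference."""

    table: pd.DataFrame  # index quantity; columns diseased, reference, difference [, lower, upper]
    level: float | None = None

    @property
    def total(self) -> float:
        return float(self.table.loc["lyl_total", "difference"])


def _normalize(side, weights: AgeWeights | None):
    """Reduce any accepted input to (LYLEstimate, replicates-or-None)."""
    if isinstance(side, BootstrapResult):
        return side.point, side.replicates
    if isinstance(side, LYLTable):
        if weights is None:
            raise ValueError("an LYL table needs onset weights to be summarized")
        return weighted_summary(side, weights), None
    if isinstance(side, LYLEstimate):
        return side, None
    raise TypeError(f"unsupported input of type {type(side).__name__}")


def _diff_ci(
    d_reps: pd.DataFrame | None,
    r_reps: pd.DataFrame | None,
    d_point: dict,
    r_point: dict,
    names: list[str],
    level: float,
):
    """Percentile CI of the difference, honouring which sides carry replicates."""
    if d_reps is None and r_reps is None:
        return None
    if d_reps is not None and r_reps is not None:
        if len(d_reps) != len(r_reps):
            raise ValueError(
                "both sides bootstrapped with unequal niter "
                f"({len(d_reps)} vs {len(r_reps)}); replicates are paired by index"
            )
        diffs = d_reps[names].to_numpy() - r_reps[names].to_numpy()
    elif d_reps is not None:
        diffs = d_reps[names].to_numpy() - np.array([r_point[k] for k in names])
    else:
        diffs = np.array([d_point[k] for k in names]) - r_reps[names].to_numpy()
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha], axis=0, method=_QUANTILE_METHOD)
    return lo, hi


def excess_lyl(diseased, reference, weights: AgeWeights | None = None, level: float = 0.95) -> ExcessLYL:
    """Difference in LYL (total and per cause) between two populations.

    Parameters
    ----------
    diseased, reference : LYLEstimate | LYLTable | BootstrapResult
        Matching condition ages / age ranges and tau are required.  Range
        inputs are collapsed with ``weights`` first.
    weights : AgeWeights, optional
        Onset weights for range inputs (applied to both sides).
    level : float
        CI level used when at least one side carries replicates.

    The reported ``difference`` is diseased LYL minus reference LYL; for
    the life-expectancy row the sign is flipped so that a harmful disease
    shows positive excess throughout.
    """
    d_point, d_reps = _normalize(diseased, weights)
    r_point, r_reps = _normalize(reference, weights)
    if abs(d_point.tau - r_point.tau) > 1e-9:
        raise ValueError(f"mismatched tau: {d_point.tau:g} vs {r_point.tau:g}")
    if abs(d_point.condition_age - r_point.condition_age) > 1e-9:
        raise ValueError(
            "mismatched conditioning ages: "
            f"{d_point.condition_age:g} vs {r_point.condition_age:g}"
        )
    if set(d_point.lyl_by_cause) != set(r_point.lyl_by_cause):
        raise ValueError("the two populations carry different cause labels")

    dq, rq = d_point.quantities(), r_point.quantities()
    names = list(dq)
    rows = []
    for k in names:
        diff = dq[k] - rq[k]
        rows.append({"quantity": k, "diseased": dq[k], "reference": rq[k], "difference": diff})
    table = pd.DataFrame(rows).set_index("quantity")

    ci = _diff_ci(d_reps, r_reps, dq, rq, names, level)
    if ci is not None:
        table["lower"], table["upper"] = ci
    return ExcessLYL(table=table, level=level if ci is not None else None)


def _lifetable_lyl(lt: LifeTable, condition_age: float, tau: float) -> tuple[float, float]:
    curve = lifetable_to_curve(lt, condition_age, tau)
    le = curve.restricted_area(condition_age, tau)
    return le, (tau - condition_age) - le


def excess_lyl_vs_lifetable(
    diseased, lt: LifeTable, weights: AgeWeights | None = None, level: float = 0.95
) -> ExcessLYL:
    """Excess LYL of a diseased cohort over a standard life table.

    ``diseased`` may be a single-age estimate, a per-age table, or
    either wrapped in a bootstrap; passing ``weights`` selects the
    range-weighted comparison (the reference LYL is then the
    case-weighted mean of the life-table LYL over the onset ages).
    Life tables carry no cause-of-death
    information, so the reference and the difference are total-only; the
    diseased side's cause decomposition is still reported.
    """
    d_point, d_reps = _normalize(diseased, weights)

    tau = d_point.tau
    if weights is not None:
        # range input: reference LYL is the case-weighted mean over onset ages
        ages = np.array([a for a, c in weights.counts.items() if c > 0], dtype=float)
        n = np.array([weights.counts[int(a)] for a in ages], dtype=float)
        per_age = np.array([_lifetable_lyl(lt, a, tau)[1] for a in ages])
        ref_lyl = float(np.dot(n, per_age) / n.sum())
        ref_le = float(np.dot(n, tau - ages) / n.sum()) - ref_lyl
    else:
        ref_le, ref_lyl = _lifetable_lyl(lt, d_point.condition_age, tau)

    dq = d_point.quantities()
    rows = [
        {
            "quantity": "life_expectancy",
            "diseased": dq["life_expectancy"],
            "reference": ref_le,
            "difference": dq["life_expectancy"] - ref_le,
        },
        {
            "quantity": "lyl_total",
            "diseased": dq["lyl_total"],
            "reference": ref_lyl,
            "difference": dq["lyl_total"] - ref_lyl,
        },
    ]
    for cause, v in d_point.lyl_by_cause.items():
        rows.append(
            {"quantity": f"lyl_{cause}", "diseased": v, "reference": np.nan, "difference": np.nan}
        )
    table = pd.DataFrame(rows).set_index("quantity")

    if d_reps is not None:
        alpha = (1.0 - level) / 2.0
        diffs = d_reps["lyl_total"].to_numpy() - ref_lyl
        lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha], method=_QUANTILE_METHOD)
        table["lower"] = np.nan
        table["upper"] = np.nan
        table.loc["lyl_total", ["lower", "upper"]] = [lo, hi]
        le_diffs = d_reps["life_expectancy"].to_numpy() - ref_le
        lo, hi = np.quantile(le_diffs, [alpha, 1.0 - alpha], method=_QUANTILE_METHOD)
        table.loc["life_expectancy", ["lower", "upper"]] = [lo, hi]
        return ExcessLYL(table=table, level=level)
    return ExcessLYL(table=table, level=None)
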