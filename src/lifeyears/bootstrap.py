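"""Non-parametric bootstrap confidence intervals for LYL estimates.

The resampling unit is the individual record (entry, exit, status,
onset), drawn with replacement ``n`` out of ``n``; the estimator is
re-run on each replicate and percentile CIs are read off the replicate
distribution.  Per-iteration random streams are spawned from one master
seed, so runs are reproducible and ``niter`` can be extended without
changing earlier replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import Cohort
from .point import LYLEstimate, lyl_at_age
from .ranges import AgeWeights, lyl_over_range, weighted_summary

__all__ = [
    "BootstrapResult",
    "StabilityTrace",
    "bootstrap_lyl",
    "point_estimator",
    "range_estimator",
    "ci_stability",
]

# Percentile CIs use numpy's default linearly-interpolated quantile.
_QUANTILE_METHOD = "linear"


@dataclass
class BootstrapResult:
    """Point estimate, replicate matrix and percentile CIs."""

    point: LYLEstimate
    replicates: pd.DataFrame  # niter rows, one column per quantity
    level: float
    ci: pd.DataFrame  # index = quantity, columns = lower/upper
    seed: int
    niter: int


def point_estimator(condition_age: float, tau: float) -> Callable[[Cohort], LYLEstimate]:
    """Estimator spec for a single-age LYL fit."""

    def est(cohort: Cohort) -> LYLEstimate:
        return lyl_at_age(cohort, condition_age, tau)

    return est


def range_estimator(
    age_begin: int, age_end: int, tau: float, weights: AgeWeights
) -> Callable[[Cohort], LYLEstimate]:
    """Estimator spec for a range fit collapsed with fixed onset weights.

    The weights are held fixed across replicates (they describe the
    observed age-at-onset distribution being averaged over, not a
    resampled quantity).
    """

    def est(cohort: Cohort) -> LYLEstimate:
        table = lyl_over_range(cohort, age_begin, age_end, tau)
        return weighted_summary(table, weights)

    return est


def bootstrap_lyl(
    cohort: Cohort,
    estimator: Callable[[Cohort], LYLEstimate],
    niter: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_retries: int = 50,
) -> BootstrapResult:
    """Percentile bootstrap around ``estimator(cohort)``.

    Parameters
    ----------
    estimator : callable
        Maps a cohort to an :class:`LYLEstimate`; use
        :func:`point_estimator` / :func:`range_estimator` for the
        standard cases.
    niter : int
        Number of bootstrap replicates (>= 2).
    level : float
        Confidence level in (0, 1); default 0.95.
    seed : int
        Master seed; identical seeds give bit-identical replicates.
    max_retries : int
        Replicates whose resample leaves an empty risk set are redrawn at
        most this many times before erroring out.
    """
    if niter < 2:
        raise ValueError("niter must be >= 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")

    point = estimator(cohort)
    names = list(point.quantities())
    n = cohort.n
    streams = np.random.SeedSequence(seed).spawn(niter)
    rows = np.empty((niter, len(names)))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, n)
            try:
                rep = estimator(cohort.subset(idx))
                break
            except ValueError:
                if attempt == max_retries:
                    raise ValueError(
                        f"bootstrap iteration {i} failed after {max_retries} redraws "
                        "(empty risk set); the cohort is too sparse at this age"
                    )
        rows[i] = [rep.quantities()[k] for k in names]

    replicates = pd.DataFrame(rows, columns=names)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(rows, [alpha, 1.0 - alpha], axis=0, method=_QUANTILE_METHOD)
    ci = pd.DataFrame({"lower": lo, "upper": hi}, index=names)
    return BootstrapResult(
        point=point, replicates=replicates, level=level, ci=ci, seed=seed, niter=niter
    )


@dataclass
class StabilityTrace:
    """Running CI endpoints as a function of the number of replicates used."""

    trace: pd.DataFrame  # columns: iteration, <q>_lower, <q>_upper ...
    converged: bool
    tolerance: float


def ci_stability(
    result: BootstrapResult, tolerance: float = 0.05, min_iterations: int = 10
) -> StabilityTrace:
    """Diagnose whether ``niter`` was large enough.

    Recomputes the percentile endpoints using only the first ``m``
    replicates for every ``m`` from ``min_iterations`` to ``niter``.  The
    run is flagged converged when, over the last 20% of the trace, no
    endpoint moves by more than ``tolerance`` years.
    """
    if result.niter < min_iterations:
        raise ValueError(f"need at least {min_iterations} replicates")
    reps = result.replicates.to_numpy()
    alpha = (1.0 - result.level) / 2.0
    ms = np.arange(min_iterations, result.niter + 1)
    recs = np.empty((ms.size, 2 * reps.shape[1]))
    for j, m in enumerate(ms):
        lo, hi = np.quantile(reps[:m], [alpha, 1.0 - alpha], axis=0, method=_QUANTILE_METHOD)
        recs[j, 0::2] = lo
        recs[j, 1::2] = hi
    cols = []
    for name in result.replicates.columns:
        cols += [f"{name}_lower", f"{name}_upper"]
    trace = pd.DataFrame(recs, columns=cols)
    trace.insert(0, "iteration", ms)

    tail = max(2, int(np.ceil(0.2 * ms.size)))
    window = recs[-tail:]
    drift = float(np.max(window.max(axis=0) - window.min(axis=0)))
    return StabilityTrace(trace=trace, converged=drift < tolerance, tolerance=tolerance)
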