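"""Reference populations given as standard life tables.

A life table supplies, per integer age, the survivor proportion and/or
the age-specific mortality rate.  Between integer ages survival is
modelled as piecewise exponential: within ``[x, x+1)`` the hazard is the
constant ``rate_x``, so either column alone determines the whole curve
(``survivor(x+1) = survivor(x) * exp(-rate_x)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LifeTable", "PiecewiseExponentialCurve", "lifetable_to_curve"]

_CONSISTENCY_TOL = 1e-6


@dataclass
class LifeTable:
    """Age-indexed survivor proportions and/or mortality rates.

    Parameters
    ----------
    ages : array-like of int
        Consecutive integer ages.
    survivor : array-like, optional
        Proportion still alive at each age; non-increasing.  Normalized
        to its first value if that is not 1.
    rate : array-like, optional
        Mortality rate (per person-year) within ``[age, age+1)``.

    At least one of ``survivor`` / ``rate`` is required; when both are
    given they must agree (``survivor(a+1)/survivor(a)`` within 1e-6 of
    ``exp(-rate(a))``).
    """

    ages: np.ndarray
    survivor: np.ndarray | None = None
    rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        if self.ages.size < 2:
            raise ValueError("life table needs at least two ages")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("life-table ages must be consecutive integers")
        if self.survivor is None and self.rate is None:
            raise ValueError("life table needs a survivor or a rate column")

        if self.survivor is not None:
            s = np.asarray(self.survivor, dtype=float)
            if s.shape != self.ages.shape:
                raise ValueError("survivor column length must match ages")
            if np.any(s < 0) or np.any(s > 1 + 1e-12):
                raise ValueError("survivor proportions must lie in [0, 1]")
            if np.any(np.diff(s) > 1e-12):
                raise ValueError("survivor proportions must be non-increasing")
            if s[0] <= 0:
                raise ValueError("survivor proportion at the first age must be positive")
            self.survivor = s / s[0]

        if self.rate is not None:
            r = np.asarray(self.rate, dtype=float)
            if r.shape != self.ages.shape:
                raise ValueError("rate column length must match ages")
            if np.any(r < 0):
                raise ValueError("mortality rates must be non-negative")
            self.rate = r

        if self.survivor is not None and self.rate is not None:
            s, r = self.survivor, self.rate
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = s[1:] / s[:-1]
            expected = np.exp(-r[:-1])
            ok = np.isclose(ratio, expected, atol=_CONSISTENCY_TOL, rtol=0) | (s[:-1] == 0)
            if not ok.all():
                bad = self.ages[:-1][~ok][:5].tolist()
                raise ValueError(
                    "survivor and rate columns are inconsistent "
                    f"(survivor(a+1)/survivor(a) vs exp(-rate(a)) at age(s) {bad})"
                )

    # ------------------------------------------------------------------
    @property
    def max_age(self) -> float:
        """Largest age up to which the survival curve is determined."""
        if self.survivor is not None:
            return float(self.ages[-1])
        # a rate for [last, last+1) extends the curve one year further
        return float(self.ages[-1] + 1)

    def yearly_rates(self) -> np.ndarray:
        """Rates on ``[ages[0], max_age)``, derived from survivors if needed.

        Survivor proportions take precedence when both columns are
        present (fewer numerical operations).
        """
        if self.survivor is not None:
            s = self.survivor
            with np.errstate(divide="ignore"):
                r = np.where(s[:-1] > 0, -np.log(np.maximum(s[1:], 0.0) / np.where(s[:-1] > 0, s[:-1], 1.0)), np.inf)
            return r
        return np.asarray(self.rate, dtype=float)


@dataclass
class PiecewiseExponentialCurve:
    """Conditional survival curve from yearly rates, continuous in age.

    ``survival_at(t)`` is the probability of surviving to age ``t`` given
    alive at ``condition_age``; within each year the curve decays
    exponentially at that year's rate.
    """

    condition_age: float
    first_age: int
    rates: np.ndarray  # rate for [first_age + k, first_age + k + 1)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        # cumulative hazard at integer grid ages
        self._cumhaz = np.concatenate(([0.0], np.cumsum(self.rates)))
        self._H_cond = self._cumhaz_at(self.condition_age)

    @property
    def max_age(self) -> float:
        return float(self.first_age + self.rates.size)

    def _cumhaz_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = np.clip(t - self.first_age, 0.0, float(self.rates.size))
        k = np.minimum(np.floor(u).astype(int), self.rates.size - 1)
        frac = u - k
        # guard inf * 0 when a survivor column hits zero (rate = inf)
        with np.errstate(invalid="ignore"):
            part = np.where(frac > 0, self.rates[k] * frac, 0.0)
        return self._cumhaz[k] + part

    def survival_at(self, t):
        """S(t | alive at condition_age); 1 for t <= condition_age."""
        h = self._cumhaz_at(t) - self._H_cond
        out = np.exp(-np.clip(h, 0.0, None))
        return out if np.ndim(out) else float(out)

    def restricted_area(self, from_age: float, to_age: float) -> float:
        """Exact integral of the conditional survival on ``[from_age, to_age]``.

        Uses the closed form ``S(x) * (1 - exp(-r w)) / r`` per (partial)
        year segment, with the limit ``S(x) * w`` when the rate is 0.
        """
        if to_age <= from_age:
            raise ValueError("to_age must exceed from_age")
        if from_age < self.condition_age - 1e-12:
            raise ValueError("from_age lies before the conditioning age")
        if to_age > self.max_age + 1e-9:
            raise ValueError(
                f"to_age {to_age:g} beyond the table's last supported age {self.max_age:g}"
            )
        # segment boundaries: from_age, integer grid ages strictly inside, to_age
        grid = self.first_age + np.arange(self.rates.size + 1, dtype=float)
        inner = grid[(grid > from_age) & (grid < to_age)]
        bounds = np.concatenate(([from_age], inner, [to_age]))
        starts, ends = bounds[:-1], bounds[1:]
        widths = ends - starts
        k = np.minimum(
            np.floor(np.clip(starts - self.first_age, 0.0, None)).astype(int),
            self.rates.size - 1,
        )
        r = self.rates[k]
        s0 = np.asarray(self.survival_at(starts), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            seg = np.where(r > 0, s0 * (1.0 - np.exp(-r * widths)) / np.where(r > 0, r, 1.0), s0 * widths)
        return float(seg.sum())


def lifetable_to_curve(
    lt: LifeTable, condition_age: float, tau: float
) -> PiecewiseExponentialCurve:
    """Conditional survival curve from a life table.

    Raises
    ------
    ValueError
        If ``[condition_age, tau]`` falls outside the ages the table
        determines.
    """
    if tau <= condition_age:
        raise ValueError("tau must exceed condition_age")
    if condition_age < lt.ages[0] - 1e-9:
        raise ValueError(
            f"condition age {condition_age:g} before the table's first age {lt.ages[0]}"
        )
    if tau > lt.max_age + 1e-9:
        raise ValueError(
            f"tau {tau:g} beyond the table's last age {lt.max_age:g}; "
            "cap tau at the table's maximum age"
        )
    curve = PiecewiseExponentialCurve(
        condition_age=float(condition_age),
        first_age=int(lt.ages[0]),
        rates=lt.yearly_rates(),
    )
    if np.isinf(curve._H_cond) or np.isnan(curve._H_cond):
        raise ValueError(f"no survivors at condition age {condition_age:g}")
    return curve
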