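"""Synthetic cohorts for validating the LYL estimators.

Two generators are provided:

* :func:`simulate_population` builds a register-like population followed
  from birth with a disease of variable onset age, two competing causes
  of death (natural / unnatural) whose hazards change at onset, and
  administrative censoring at a fixed age.  The default scenario is
  roughly calibrated so that about a third of the population develops
  the disease and a small minority of deaths are unnatural.
* :func:`constant_hazard_cohort` draws a cohort with known constant
  cause-specific hazards, for which :func:`closed_form_lyl` gives the
  exact restricted life expectancy and cause-specific losses — the
  analytic oracle used throughout the test suite.

Hazards may be constants (per year) or per-year piecewise-constant
arrays indexed by attained age; event ages are drawn by inverting the
cumulative hazard.  Competing causes use independent latent times per
cause, which is an exact construction for cause-specific hazards that
depend only on attained age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .point import LYLEstimate

__all__ = [
    "SimulationScenario",
    "simulate_population",
    "constant_hazard_cohort",
    "closed_form_lyl",
]

#: Default post-onset / pre-onset cause-specific hazards (per person-year).
#: Chosen so the generated population resembles a register cohort of
#: ~100k persons: ~32% develop the disease, ~6% of deaths are unnatural,
#: and a few percent survive to the censoring age of 95.
DEFAULT_PRE_ONSET = {"natural": 0.0235, "unnatural": 0.0015}
DEFAULT_POST_ONSET = {"natural": 0.0370, "unnatural": 0.0040}
DEFAULT_ONSET_RATE = 0.012


@dataclass
class SimulationScenario:
    """Parameters of the register-like population generator.

    Hazards are either scalars (constant in age) or 1-d arrays giving a
    piecewise-constant rate per whole year of attained age from 0 to
    ``tau_censor``.
    """

    n: int = 100_000
    tau_censor: float = 95.0
    onset_rate: float | np.ndarray = DEFAULT_ONSET_RATE
    pre_onset_hazards: dict[str, float | np.ndarray] = field(
        default_factory=lambda: dict(DEFAULT_PRE_ONSET)
    )
    post_onset_hazards: dict[str, float | np.ndarray] = field(
        default_factory=lambda: dict(DEFAULT_POST_ONSET)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.tau_censor <= 0:
            raise ValueError("tau_censor must be positive")
        if set(self.pre_onset_hazards) != set(self.post_onset_hazards):
            raise ValueError("pre- and post-onset hazards must use the same causes")
        for rates in (self.onset_rate, *self.pre_onset_hazards.values(), *self.post_onset_hazards.values()):
            if np.any(np.asarray(rates, dtype=float) < 0):
                raise ValueError("all rates must be non-negative")


def _draw_event_ages(rng, rate, start_ages: np.ndarray, horizon: float) -> np.ndarray:
    """Event ages for hazard ``rate`` starting at ``start_ages``.

    Inverts the cumulative hazard of an exponential draw; ages beyond
    ``horizon`` are returned as +inf (no event in the window).
    """
    u = rng.exponential(size=start_ages.size)  # Exp(1) cumulative hazards
    rate = np.asarray(rate, dtype=float)
    if rate.ndim == 0:
        r = float(rate)
        if r == 0:
            return np.full(start_ages.size, np.inf)
        t = start_ages + u / r
    else:
        # piecewise-constant by attained year of age on [0, len(rate))
        cum = np.concatenate(([0.0], np.cumsum(rate)))
        grid = np.arange(rate.size + 1, dtype=float)
        k = np.minimum(np.floor(start_ages).astype(int), rate.size - 1)
        h_start = cum[k] + rate[k] * (start_ages - k)
        target = h_start + u
        j = np.searchsorted(cum, target, side="right") - 1
        t = np.where(
            j >= rate.size,
            np.inf,
            grid[np.minimum(j, rate.size - 1)]
            + np.where(
                rate[np.minimum(j, rate.size - 1)] > 0,
                (target - cum[np.minimum(j, rate.size - 1)])
                / np.where(rate[np.minimum(j, rate.size - 1)] > 0, rate[np.minimum(j, rate.size - 1)], 1.0),
                np.inf,
            ),
        )
    return np.where(t > horizon, np.inf, t)


def simulate_population(scenario: SimulationScenario) -> Cohort:
    """Draw a full population followed from birth; deterministic given the seed.

    Each person gets a latent onset age and latent cause-specific death
    ages under the pre-onset hazards; if onset occurs first, residual
    death ages are redrawn under the post-onset hazards from the onset
    age on.  The earliest event wins; survivors at ``tau_censor`` are
    administratively censored.  The returned cohort has entry 0 for
    everyone and carries onset ages (nan when the disease never occurs).
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    tau = scenario.tau_censor
    causes = list(scenario.pre_onset_hazards)
    zeros = np.zeros(n)

    onset = _draw_event_ages(rng, scenario.onset_rate, zeros, tau)
    pre_deaths = np.stack(
        [_draw_event_ages(rng, scenario.pre_onset_hazards[c], zeros, np.inf) for c in causes]
    )
    pre_death = pre_deaths.min(axis=0)
    pre_cause = pre_deaths.argmin(axis=0)

    diseased = onset < np.minimum(pre_death, tau)
    death_age = pre_death.copy()
    death_cause = pre_cause.copy()
    if diseased.any():
        starts = onset[diseased]
        post = np.stack(
            [
                _draw_event_ages(rng, scenario.post_onset_hazards[c], starts, np.inf)
                for c in causes
            ]
        )
        death_age[diseased] = post.min(axis=0)
        death_cause[diseased] = post.argmin(axis=0)

    censored = death_age >= tau
    exit_age = np.where(censored, tau, death_age)
    status = np.where(censored, "alive", np.asarray(causes, dtype=object)[death_cause])
    onset_col = np.where(diseased, onset, np.nan)
    return Cohort(
        entry=zeros,
        exit=exit_age,
        status=status,
        cause_labels=causes,
        censor_label="alive",
        onset=onset_col,
    )


def constant_hazard_cohort(
    hazards: dict[str, float],
    start_age: float,
    n: int,
    censor_age: float,
    seed: int = 0,
) -> Cohort:
    """Cohort with constant cause-specific hazards from ``start_age`` on.

    Everyone enters at ``start_age``; latent exponential times per cause
    compete, and survivors at ``censor_age`` are censored.  The matching
    analytic truth is :func:`closed_form_lyl`.
    """
    if censor_age <= start_age:
        raise ValueError("censor_age must exceed start_age")
    rng = np.random.default_rng(seed)
    causes = list(hazards)
    entry = np.full(n, float(start_age))
    latent = np.stack(
        [_draw_event_ages(rng, hazards[c], entry, np.inf) for c in causes]
    )
    death = latent.min(axis=0)
    cause = latent.argmin(axis=0)
    censored = death >= censor_age
    exit_age = np.where(censored, censor_age, death)
    status = np.where(censored, "alive", np.asarray(causes, dtype=object)[cause])
    return Cohort(entry, exit_age, status, cause_labels=causes, censor_label="alive")


def closed_form_lyl(lambda_by_cause: dict[str, float], a: float, tau: float) -> LYLEstimate:
    """Analytic LYL under constant cause-specific hazards.

    With total hazard ``L = sum_k lambda_k`` and horizon ``D = tau - a``:
    restricted LE is ``(1 - exp(-L D)) / L`` (``D`` when ``L = 0``) and
    each cause takes the share ``lambda_k / L`` of the total loss.
    """
    if tau <= a:
        raise ValueError("tau must exceed a")
    lam = {k: float(v) for k, v in lambda_by_cause.items()}
    if any(v < 0 for v in lam.values()):
        raise ValueError("hazards must be non-negative")
    total = sum(lam.values())
    delta = tau - a
    if total == 0:
        le = delta
    else:
        le = (1.0 - np.exp(-total * delta)) / total
    lyl_total = delta - le
    by_cause = {
        k: (v / total) * lyl_total if total > 0 else 0.0 for k, v in lam.items()
    }
    return LYLEstimate(
        condition_age=float(a),
        tau=float(tau),
        restricted_life_expectancy=float(le),
        lyl_total=float(lyl_total),
        lyl_by_cause=by_cause,
        n_at_risk=0,
    )
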