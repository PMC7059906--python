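import numpy as np
import pytest

from lifeyears import Cohort, SimulationScenario, simulate_population


@pytest.fixture
def three_death_cohort() -> Cohort:
    """Three persons from birth, deaths at ages 1 (A), 2 (B), 3 (A)."""
    return Cohort([0, 0, 0], [1, 2, 3], ["A", "B", "A"])


@pytest.fixture(scope="session")
def small_population() -> Cohort:
    """Register-like synthetic population used across integration tests."""
    return simulate_population(SimulationScenario(n=20_000, seed=20260919))


def random_cohort(rng: np.random.Generator, n: int, causes=("A", "B")) -> Cohort:
    """Small random cohort with delayed entry, censoring and competing causes."""
    entry = np.round(rng.uniform(0, 5, n), 2)
    length = np.round(rng.uniform(0.1, 20, n), 2) + 0.01
    status = rng.choice(list(causes) + ["alive"], n)
    return Cohort(entry, entry + length, status, cause_labels=list(causes))


def brute_force_curves(cohort: Cohort, condition_age: float):
    """Independent hand-recursion oracle for the product-limit / Aalen-Johansen fit.

    Walks event ages in order, counting the risk set record by record and
    accumulating S and the per-cause CIFs with the textbook recursion.
    """
    recs = [
        (max(e, condition_age), x, s)
        for e, x, s in zip(cohort.entry, cohort.exit, cohort.status)
        if x > condition_age
    ]
    assert recs, "oracle needs someone at risk"
    causes = list(cohort.cause_labels)
    times = sorted({x for _, x, s in recs if s != cohort.censor_label})
    surv = 1.0
    cif = {c: 0.0 for c in causes}
    out = []
    for t in times:
        n_risk = sum(1 for e, x, _ in recs if e < t <= x)
        d = {c: sum(1 for _, x, s in recs if x == t and s == c) for c in causes}
        for c in causes:
            cif[c] += surv * d[c] / n_risk
        surv *= 1.0 - sum(d.values()) / n_risk
        out.append((t, surv, dict(cif)))
    return out
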