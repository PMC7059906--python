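"""Product-limit and Aalen-Johansen estimation with left truncation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifeyears import (
    Cohort,
    StepCurve,
    fit_competing_risks,
    fit_conditional_survival,
    numbers_at_risk,
    restricted_area,
)

from conftest import brute_force_curves, random_cohort


class TestHandExamples:
    def test_product_limit_three_deaths(self):
        c = Cohort([0, 0, 0], [1, 2, 3], ["dead"] * 3)
        s = fit_conditional_survival(c, 0)
        assert np.allclose(s.jump_ages, [1, 2, 3])
        assert np.allclose(s.values, [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_all_censored_gives_flat_curve(self):
        c = Cohort([0, 0], [10, 20], ["alive", "alive"], cause_labels=["dead"])
        s = fit_conditional_survival(c, 0)
        assert s.jump_ages.size == 0
        assert s.value_at(15.0) == 1.0

    def test_aalen_johansen_two_causes(self, three_death_cohort):
        cur = fit_competing_risks(three_death_cohort, 0)
        assert cur.cifs["A"].value_at(3.0) == pytest.approx(2 / 3, abs=1e-12)
        assert cur.cifs["B"].value_at(3.0) == pytest.approx(1 / 3, abs=1e-12)
        assert cur.survival.value_at(3.0) == pytest.approx(0.0, abs=1e-12)
        # intermediate values from the hand recursion
        assert cur.cifs["A"].value_at(1.5) == pytest.approx(1 / 3, abs=1e-12)
        assert cur.cifs["B"].value_at(2.5) == pytest.approx(1 / 3, abs=1e-12)

    def test_single_cause_cif_is_one_minus_survival(self):
        rng = np.random.default_rng(5)
        c = random_cohort(rng, 40, causes=("dead",))
        cur = fit_competing_risks(c, 0)
        assert np.allclose(cur.cifs["dead"].values, 1.0 - cur.survival.values, atol=1e-12)

    def test_empty_risk_set_raises(self):
        c = Cohort([0], [5], ["dead"])
        with pytest.raises(ValueError, match="at risk"):
            fit_conditional_survival(c, 10.0)


class TestRestrictedArea:
    def test_two_step_curve(self):
        curve = StepCurve(0.0, np.array([2.0]), np.array([0.5]))
        assert restricted_area(curve, 0, 5) == pytest.approx(3.5)

    def test_flat_curve_area_is_interval_length(self):
        curve = StepCurve(0.0, np.array([]), np.array([]))
        assert restricted_area(curve, 1.0, 7.5) == pytest.approx(6.5)

    def test_three_death_curve_area(self):
        c = Cohort([0, 0, 0], [1, 2, 3], ["dead"] * 3)
        s = fit_conditional_survival(c, 0)
        assert restricted_area(s, 0, 3) == pytest.approx(2.0, abs=1e-12)

    def test_inverted_interval_raises(self):
        curve = StepCurve(0.0, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            restricted_area(curve, 3.0, 3.0)


class TestNumbersAtRisk:
    def test_counts_with_delayed_entry(self):
        c = Cohort([0, 0, 50], [40, 60, 70], ["dead"] * 3)
        tab = numbers_at_risk(c, [45.0, 55.0, 10.0])
        assert tab.set_index("age").loc[45.0, "n_at_risk"] == 1
        assert tab.set_index("age").loc[55.0, "n_at_risk"] == 2
        assert tab.set_index("age").loc[10.0, "n_at_risk"] == 2

    def test_age_before_all_entries(self):
        c = Cohort([30, 40], [50, 60], ["dead", "dead"])
        assert numbers_at_risk(c, [20.0])["n_at_risk"].iloc[0] == 0

    def test_events_so_far(self):
        c = Cohort([0, 0, 0], [10, 20, 30], ["dead", "alive", "dead"], cause_labels=["dead"])
        tab = numbers_at_risk(c, [25.0])
        assert tab["n_events_so_far"].iloc[0] == 1


@st.composite
def cohort_strategy(draw):
    n = draw(st.integers(2, 12))
    entries = draw(st.lists(st.sampled_from([0.0, 0.5, 1.0, 2.0, 3.5]), min_size=n, max_size=n))
    # distinct durations avoid ties so the oracle comparison is exact
    durs = draw(
        st.lists(
            st.floats(0.25, 15.0, allow_nan=False), min_size=n, max_size=n, unique=True
        )
    )
    statuses = draw(st.lists(st.sampled_from(["A", "B", "alive"]), min_size=n, max_size=n))
    return Cohort(
        entries, [e + d for e, d in zip(entries, durs)], statuses, cause_labels=["A", "B"]
    )


@settings(max_examples=150, derandomize=True, deadline=None)
@given(cohort_strategy(), st.sampled_from([0.0, 0.5, 1.0, 2.0]))
def test_estimator_matches_hand_recursion(cohort, a):
    """Fit equals the independent textbook recursion on small cohorts."""
    if not np.any(cohort.exit > a):
        return
    cur = fit_competing_risks(cohort, a)
    for t, s_true, cif_true in brute_force_curves(cohort, a):
        assert cur.survival.value_at(t) == pytest.approx(s_true, abs=1e-12)
        for c in cohort.cause_labels:
            assert cur.cifs[c].value_at(t) == pytest.approx(cif_true[c], abs=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(cohort_strategy(), st.sampled_from([0.0, 1.0]))
def test_additivity_and_monotonicity(cohort, a):
    """S + sum_k F_k = 1 at every jump; S non-increasing, CIFs non-decreasing."""
    if not np.any(cohort.exit > a):
        return
    cur = fit_competing_risks(cohort, a)
    total = cur.survival.values + sum(c.values for c in cur.cifs.values())
    assert np.max(np.abs(total - 1.0)) <= 1e-12 if total.size else True
    assert np.all(np.diff(np.concatenate(([1.0], cur.survival.values))) <= 1e-15)
    for c in cur.cifs.values():
        assert np.all(np.diff(np.concatenate(([0.0], c.values))) >= -1e-15)


def test_late_entrant_does_not_change_curve_below_entry():
    """Left truncation: a delayed entrant leaves the curve before their entry unchanged."""
    rng = np.random.default_rng(8)
    base = random_cohort(rng, 30)
    extra = Cohort(
        np.append(base.entry, 18.0),
        np.append(base.exit, 25.0),
        np.append(base.status, "A"),
        cause_labels=base.cause_labels,
    )
    s0 = fit_conditional_survival(base, 0)
    s1 = fit_conditional_survival(extra, 0)
    for t in np.linspace(0.1, 17.9, 40):
        assert s1.value_at(t) == pytest.approx(s0.value_at(t), abs=1e-12)


def test_tied_censoring_stays_in_risk_set():
    """A censoring tied with a death still counts in that death's risk set."""
    c = Cohort([0, 0, 0], [5, 5, 9], ["dead", "alive", "dead"], cause_labels=["dead"])
    s = fit_conditional_survival(c, 0)
    # risk set at 5 is all three persons: S(5) = 2/3, then S(9) = 2/3 * 0 = 0... n=1
    assert s.value_at(5.0) == pytest.approx(2 / 3, abs=1e-12)
    assert s.value_at(9.0) == pytest.approx(0.0, abs=1e-12)


def test_constant_hazard_convergence():
    """Estimated survival approaches exp(-lambda t) on a large simulated cohort."""
    from lifeyears import constant_hazard_cohort

    lam = 0.05
    c = constant_hazard_cohort({"dead": lam}, 45.0, 50_000, 95.0, seed=42)
    s = fit_conditional_survival(c, 45.0)
    grid = np.linspace(46, 94, 60)
    err = np.abs(np.asarray(s.value_at(grid)) - np.exp(-lam * (grid - 45.0)))
    assert err.max() < 0.01


def test_matches_lifelines_with_delayed_entry(small_population):
    """Cross-check against lifelines' Kaplan-Meier and Aalen-Johansen fitters."""
    lifelines = pytest.importorskip("lifelines")
    cohort = small_population.diseased().subset(np.arange(3000))
    a = 45.0
    keep = cohort.exit > a
    durations = cohort.exit[keep]
    entry = np.maximum(cohort.entry[keep], a)
    events = cohort.cause_index[keep]

    km = lifelines.KaplanMeierFitter().fit(durations, events >= 0, entry=entry)
    ours = fit_conditional_survival(cohort, a)
    grid = np.linspace(46, 94, 25)
    theirs = km.survival_function_at_times(grid).to_numpy()
    assert np.allclose(np.asarray(ours.value_at(grid)), theirs, atol=1e-8)

    aj = lifelines.AalenJohansenFitter(calculate_variance=False).fit(
        durations, np.where(events >= 0, events + 1, 0), event_of_interest=1, entry=entry
    )
    cif1 = aj.cumulative_density_.iloc[:, 0]
    mine = fit_competing_risks(cohort, a).cifs[cohort.cause_labels[0]]
    idx = np.searchsorted(cif1.index.to_numpy(), grid, side="right") - 1
    theirs = cif1.to_numpy()[idx]
    assert np.allclose(np.asarray(mine.value_at(grid)), theirs, atol=1e-8)
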