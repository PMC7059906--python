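"""Life tables, piecewise-exponential survival and excess-LYL comparisons."""

import numpy as np
import pytest

from lifeyears import (
    Cohort,
    LifeTable,
    bootstrap_lyl,
    excess_lyl,
    excess_lyl_vs_lifetable,
    lifetable_to_curve,
    lyl_at_age,
    point_estimator,
    weights_from_onsets,
)

from conftest import random_cohort


class TestLifeTable:
    def test_one_year_closed_form(self):
        lt = LifeTable(ages=np.arange(0, 3), rate=[0.1, 0.0, 0.0])
        curve = lifetable_to_curve(lt, 0, 1)
        assert curve.restricted_area(0, 1) == pytest.approx((1 - np.exp(-0.1)) / 0.1)
        assert curve.survival_at(1.0) == pytest.approx(np.exp(-0.1))

    def test_zero_rates_area_is_horizon(self):
        lt = LifeTable(ages=np.arange(40, 60), rate=np.zeros(20))
        curve = lifetable_to_curve(lt, 42, 58)
        assert curve.restricted_area(42, 58) == pytest.approx(16.0)

    def test_constant_rate_geometric_identity(self):
        lam = 0.07
        lt = LifeTable(ages=np.arange(30, 80), rate=np.full(50, lam))
        curve = lifetable_to_curve(lt, 30, 80)
        assert curve.restricted_area(30, 80) == pytest.approx(
            (1 - np.exp(-lam * 50)) / lam, abs=1e-9
        )

    def test_rates_and_survivors_give_equal_areas(self):
        rng = np.random.default_rng(14)
        rates = rng.uniform(0.0, 0.2, 40)
        surv = np.concatenate(([1.0], np.exp(-np.cumsum(rates))))
        lt_r = LifeTable(ages=np.arange(0, 40), rate=rates)
        lt_s = LifeTable(ages=np.arange(0, 41), survivor=surv)
        a_r = lifetable_to_curve(lt_r, 3.0, 38.0).restricted_area(3.0, 38.0)
        a_s = lifetable_to_curve(lt_s, 3.0, 38.0).restricted_area(3.0, 38.0)
        assert a_r == pytest.approx(a_s, abs=1e-9)

    def test_fractional_condition_age(self):
        lam = 0.05
        lt = LifeTable(ages=np.arange(0, 50), rate=np.full(50, lam))
        curve = lifetable_to_curve(lt, 10.4, 30.0)
        assert curve.survival_at(12.9) == pytest.approx(np.exp(-lam * 2.5))

    def test_inconsistent_columns_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            LifeTable(ages=[0, 1, 2], survivor=[1.0, 0.5, 0.25], rate=[0.1, 0.1, 0.1])

    def test_consistent_columns_accepted(self):
        rates = np.array([0.1, 0.2, 0.0])
        surv = np.concatenate(([1.0], np.exp(-np.cumsum(rates[:-1]))))
        LifeTable(ages=[0, 1, 2], survivor=surv, rate=rates)

    def test_non_monotone_survivor_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            LifeTable(ages=[0, 1, 2], survivor=[1.0, 0.8, 0.9])

    def test_tau_beyond_table_rejected(self):
        lt = LifeTable(ages=np.arange(0, 10), rate=np.zeros(10))
        with pytest.raises(ValueError, match="beyond"):
            lifetable_to_curve(lt, 0, 50)

    def test_missing_both_columns_rejected(self):
        with pytest.raises(ValueError, match="survivor or a rate"):
            LifeTable(ages=[0, 1, 2])


class TestExcessLYL:
    def test_identical_inputs_give_zero(self):
        rng = np.random.default_rng(21)
        est = lyl_at_age(random_cohort(rng, 120), 1.0, 20.0)
        result = excess_lyl(est, est)
        assert np.allclose(result.table["difference"], 0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(22)
        a = lyl_at_age(random_cohort(rng, 120), 1.0, 20.0)
        b = lyl_at_age(random_cohort(rng, 150), 1.0, 20.0)
        fwd = excess_lyl(a, b).table["difference"]
        rev = excess_lyl(b, a).table["difference"]
        assert np.allclose(fwd, -rev, atol=1e-12)

    def test_cause_differences_sum_to_total(self):
        rng = np.random.default_rng(23)
        a = lyl_at_age(random_cohort(rng, 200), 1.0, 20.0)
        b = lyl_at_age(random_cohort(rng, 180), 1.0, 20.0)
        table = excess_lyl(a, b).table
        causes = [q for q in table.index if q.startswith("lyl_") and q != "lyl_total"]
        assert table.loc[causes, "difference"].sum() == pytest.approx(
            table.loc["lyl_total", "difference"], abs=1e-9
        )

    def test_mismatched_tau_rejected(self):
        rng = np.random.default_rng(24)
        c = random_cohort(rng, 100)
        with pytest.raises(ValueError, match="tau"):
            excess_lyl(lyl_at_age(c, 1.0, 20.0), lyl_at_age(c, 1.0, 21.0))

    def test_one_sided_bootstrap_ci(self):
        rng = np.random.default_rng(25)
        c = random_cohort(rng, 300)
        boot = bootstrap_lyl(c, point_estimator(1.0, 20.0), niter=40, seed=4)
        ref = lyl_at_age(random_cohort(rng, 300), 1.0, 20.0)
        table = excess_lyl(boot, ref).table
        assert (table["lower"] <= table["upper"]).all()
        # reference fixed: the CI is the replicate CI shifted by the reference value
        shift = boot.ci.loc["lyl_total"] - ref.quantities()["lyl_total"]
        assert table.loc["lyl_total", "lower"] == pytest.approx(shift["lower"])

    def test_unequal_niter_rejected(self):
        rng = np.random.default_rng(26)
        c = random_cohort(rng, 200)
        b1 = bootstrap_lyl(c, point_estimator(1.0, 20.0), niter=20, seed=1)
        b2 = bootstrap_lyl(c, point_estimator(1.0, 20.0), niter=30, seed=1)
        with pytest.raises(ValueError, match="niter"):
            excess_lyl(b1, b2)


class TestExcessVsLifetable:
    def test_zero_mortality_reference_gives_full_loss(self):
        rng = np.random.default_rng(27)
        est = lyl_at_age(random_cohort(rng, 150), 1.0, 20.0)
        lt = LifeTable(ages=np.arange(0, 21), rate=np.zeros(21))
        result = excess_lyl_vs_lifetable(est, lt)
        assert result.total == pytest.approx(est.lyl_total, abs=1e-12)

    def test_total_only_reference_keeps_diseased_causes(self):
        rng = np.random.default_rng(28)
        est = lyl_at_age(random_cohort(rng, 150), 1.0, 20.0)
        lt = LifeTable(ages=np.arange(0, 21), rate=np.full(21, 0.01))
        table = excess_lyl_vs_lifetable(est, lt).table
        assert np.isnan(table.loc["lyl_A", "reference"])
        assert table.loc["lyl_A", "diseased"] == pytest.approx(est.lyl_by_cause["A"])

    def test_range_weighted_mode(self, small_population):
        from lifeyears import lyl_over_range, weighted_summary

        diseased = small_population.diseased()
        w = weights_from_onsets(
            diseased.onset[(diseased.onset >= 40) & (diseased.onset < 51)], 40, 50
        )
        summary = weighted_summary(lyl_over_range(diseased, 40, 50, 95.0), w)
        lt = LifeTable(ages=np.arange(0, 96), rate=np.full(96, 0.01))
        result = excess_lyl_vs_lifetable(summary, lt, weights=w)
        # reference LYL equals the case-weighted mean of per-age life-table LYL
        ages = np.array(sorted(a for a, c in w.counts.items() if c > 0), dtype=float)
        n = np.array([w.counts[int(a)] for a in ages], dtype=float)
        per_age = [
            (95.0 - a) - lifetable_to_curve(lt, a, 95.0).restricted_area(a, 95.0) for a in ages
        ]
        expected = float(np.dot(n, per_age) / n.sum())
        assert result.table.loc["lyl_total", "reference"] == pytest.approx(expected, abs=1e-9)
        assert result.total == pytest.approx(summary.lyl_total - expected, abs=1e-9)
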