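"""Curves, exact Poisson CIs, concentration statistics, and subgroup summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedabx import descriptive, mixture, synth
from pedabx.codemap import BODY_SYSTEMS
from pedabx.config import GeneratorConfig, default_config
from conftest import make_children, make_courses


class TestPoissonExactCI:
    def test_frozen_chi_square_quantiles(self):
        lo, hi = descriptive.poisson_exact_ci(0, 1.0)
        assert lo == 0.0
        assert hi == pytest.approx(3.68888, abs=1e-4)
        lo, hi = descriptive.poisson_exact_ci(10, 1.0)
        assert lo == pytest.approx(4.79539, abs=1e-4)
        assert hi == pytest.approx(18.39036, abs=1e-4)

    def test_person_time_scaling(self):
        lo1, hi1 = descriptive.poisson_exact_ci(5, 1.0)
        lo2, hi2 = descriptive.poisson_exact_ci(5, 10.0)
        assert (lo2, hi2) == pytest.approx((lo1 / 10, hi1 / 10))

    def test_alpha_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            descriptive.poisson_exact_ci(3, 1.0, alpha=1.5)

    def test_coverage_at_least_nominal(self):
        """Exact Poisson CIs cover the true mean >= 95% of the time."""
        rng = np.random.default_rng(42)
        lam = 4.0
        draws = rng.poisson(lam, size=10_000)
        cis = {x: descriptive.poisson_exact_ci(int(x), 1.0) for x in np.unique(draws)}
        covered = np.array([cis[x][0] <= lam <= cis[x][1] for x in draws])
        se = np.sqrt(0.95 * 0.05 / len(draws))
        assert covered.mean() >= 0.95 - 3 * se


class TestCurves:
    def _setup(self):
        children = make_children(4)
        children["weight"] = [1.0, 2.0, 1.0, 1.0]
        courses = make_courses(
            [
                ("C0000000", 0, "respiratory"),
                ("C0000000", 100, "other"),
                ("C0000001", 100, "respiratory"),
                ("C0000002", 1824, "respiratory"),
            ]
        )
        return children, courses

    def test_matches_direct_weighted_mean(self):
        children, courses = self._setup()
        curve = descriptive.cumulative_course_curve(courses, children)
        w = children["weight"].to_numpy()
        for day in (0, 99, 100, 500, 1825):
            n = np.array(
                [
                    ((courses["child_id"] == c) & (courses["age_days"] <= day)).sum()
                    for c in children["child_id"]
                ]
            )
            expected = w @ n / w.sum()
            assert curve.at(day) == pytest.approx(expected), day
            # CI band from the direct weighted-mean variance formula
            se = np.sqrt((w**2 @ (n - expected) ** 2)) / w.sum()
            assert curve.ci_hi[day] - curve.at(day) == pytest.approx(1.959964 * se, rel=1e-6)

    def test_day0_boundary_is_day0_share(self):
        children, courses = self._setup()
        curve = descriptive.cumulative_course_curve(courses, children)
        assert curve.at(0) == pytest.approx(1.0 / 5.0)  # child 0 (w=1) of total w=5

    def test_first_course_flat_curves(self):
        children = make_children(3)
        empty = make_courses([])
        curve = descriptive.first_course_curve(empty, children)
        assert (curve.estimate == 0).all()
        allday0 = make_courses([(c, 0, "other") for c in children["child_id"]])
        curve = descriptive.first_course_curve(allday0, children)
        assert (curve.estimate == 1).all()

    def test_monotonicity_and_conservation(self, small_bundle, codes):
        from pedabx import linkage

        abx = small_bundle.pharmacy[small_bundle.pharmacy["drug_class"] != "antihistamines"]
        courses = linkage.classify_courses(
            linkage.build_courses(abx, small_bundle.enrollment),
            small_bundle.outpatient,
            codes,
        )
        children = small_bundle.children
        curves = {
            a: descriptive.cumulative_course_curve(courses, children, a)
            for a in descriptive.ATTRIBUTIONS
        }
        for c in curves.values():
            assert (np.diff(c.estimate) >= 0).all()
            assert (c.ci_lo <= c.estimate).all() and (c.estimate <= c.ci_hi).all()
        np.testing.assert_allclose(
            curves["respiratory"].estimate + curves["other"].estimate,
            curves["all"].estimate,
            atol=1e-12,
        )
        first = descriptive.first_course_curve(courses, children)
        assert (np.diff(first.estimate) >= 0).all()
        assert (first.estimate >= 0).all() and (first.estimate <= 1).all()

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty"):
            descriptive.cumulative_course_curve(make_courses([]), make_children(0))


class TestAgeBandRate:
    def test_simple_rate(self):
        children = make_children(100)
        rows = [(f"C{i:07d}", 50 + (i % 300), "other") for i in range(100)]
        courses = make_courses(rows)
        rate, _ci = descriptive.age_band_rate(courses, children, (0, 365))
        assert rate == pytest.approx(1.0)

    def test_zero_count_ci(self):
        children = make_children(10)
        rate, (lo, hi) = descriptive.age_band_rate(make_courses([]), children, (0, 365))
        assert rate == 0.0 and lo == 0.0
        assert hi == pytest.approx(3.68888 / 10.0, abs=1e-4)

    def test_generator_band_rates_recovered(self):
        cfg = default_config(n_children=10_000)
        children = synth.sample_children(cfg, 29)
        events = synth.sample_course_events(children, cfg, 29)
        courses = make_courses(
            list(zip(events["child_id"], events["event_age_days"], ["other"] * len(events)))
        )
        courses["fill_date"] = children.set_index("child_id").loc[
            courses["child_id"], "birth_date"
        ].to_numpy() + pd.to_timedelta(courses["age_days"], unit="D")
        for band, rate in (((180, 730), 1.9), ((730, 1825), 1.2)):
            est, _ = descriptive.age_band_rate(courses, children, band)
            years = (band[1] - band[0]) / 365.0
            se = np.sqrt(2 * rate / (len(children) * years))
            assert est == pytest.approx(rate, abs=3 * se), band

    def test_band_validation(self):
        with pytest.raises(ValueError, match="band"):
            descriptive.age_band_rate(make_courses([]), make_children(1), (100, 2000))


class TestTopShare:
    def test_single_heavy_child(self):
        res = descriptive.top_share(np.array([1, 1, 1, 1, 6]), q=0.2)
        assert res.share == pytest.approx(0.60)

    def test_equal_counts_share_equals_q(self):
        for q in (0.2, 0.37, 0.5):
            res = descriptive.top_share(np.full(50, 3.0), q=q)
            assert res.share == pytest.approx(q, abs=1e-12)

    def test_share_monotone_in_q_and_one_at_one(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, 200)
        shares = [descriptive.top_share(counts, q=q).share for q in (0.1, 0.3, 0.5, 0.9, 0.999)]
        assert all(a <= b + 1e-12 for a, b in zip(shares, shares[1:]))
        assert shares[-1] <= 1.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero"):
            descriptive.top_share(np.zeros(5), q=0.2)

    def test_negative_binomial_share_matches_analytic(self):
        """Simulated top-quintile share agrees with the pmf-recursion oracle
        (itself cross-checked against scipy's nbinom pmf)."""
        mu, k, q = 6.75, 1.33863, 0.2
        analytic = mixture.pmf_top_share(mixture.nb_pmf(mu, k, 400), q)
        ref = mixture.pmf_top_share(stats.nbinom.pmf(np.arange(401), k, k / (k + mu)), q)
        assert analytic == pytest.approx(ref, abs=1e-9)
        rng = np.random.default_rng(8)
        chunk_shares = [
            descriptive.top_share(rng.negative_binomial(k, k / (k + mu), 2_500), q=q).share
            for _ in range(20)
        ]
        est = np.mean(chunk_shares)
        se = np.std(chunk_shares, ddof=1) / np.sqrt(len(chunk_shares))
        assert est == pytest.approx(analytic, abs=3 * se)


class TestHistogram:
    def test_unit_mass_and_conservation(self):
        h = descriptive.count_histogram(np.array([3]), weights=np.array([2.5]))
        assert h.to_dict() == {3: 2.5}
        rng = np.random.default_rng(3)
        counts = rng.poisson(4, 100)
        w = rng.uniform(0.5, 2.0, 100)
        h = descriptive.count_histogram(counts, w)
        assert h.sum() == pytest.approx(w.sum())

    def test_zero_bin_matches_first_course_complement(self):
        children = make_children(10)
        courses = make_courses([("C0000000", 5, "other"), ("C0000003", 9, "other")])
        counts = descriptive.per_child_counts(courses, children)
        h = descriptive.count_histogram(counts)
        first = descriptive.first_course_curve(courses, children)
        assert h.get(0, 0.0) / len(children) == pytest.approx(1 - first.at(1825))


class TestSubgroupSummary:
    def test_empty_condition_set_errors(self, codes):
        children = make_children(5)
        flags = pd.DataFrame(
            False, index=pd.Index(children["child_id"], name="child_id"), columns=BODY_SYSTEMS
        )
        with pytest.raises(ValueError, match="empty"):
            descriptive.subgroup_summary(
                children, flags, (), make_courses([("C0000000", 5, "other")])
            )

    def test_flagged_mean_doubles_with_multiplier_two(self):
        """With a single x2 multiplier the flagged/unflagged mean ratio is the
        multiplier itself (the Z-normalisation cancels in the ratio)."""
        d = default_config(n_children=20_000, seed=37).to_dict()
        d["condition_multipliers"] = {
            s: (2.0 if s == "pulmonary_respiratory" else 1.0) for s in BODY_SYSTEMS
        }
        cfg = GeneratorConfig.from_dict(d)
        children = synth.sample_children(cfg, 37)
        events = synth.sample_course_events(children, cfg, 37)
        courses = make_courses(
            list(zip(events["child_id"], events["event_age_days"], ["other"] * len(events)))
        )
        flags = children.set_index("child_id")[[f"cond_{s}" for s in BODY_SYSTEMS]]
        flags.columns = BODY_SYSTEMS
        res = descriptive.subgroup_summary(
            children, flags, ("pulmonary_respiratory",), courses
        )
        assert res.mean_flagged / res.mean_unflagged == pytest.approx(2.0, rel=0.05)
        assert res.n_flagged + res.n_unflagged == len(children)

    def test_null_multipliers_no_difference(self):
        d = default_config(n_children=8_000, seed=41).to_dict()
        d["condition_multipliers"] = {s: 1.0 for s in BODY_SYSTEMS}
        cfg = GeneratorConfig.from_dict(d)
        children = synth.sample_children(cfg, 41)
        events = synth.sample_course_events(children, cfg, 41)
        courses = make_courses(
            list(zip(events["child_id"], events["event_age_days"], ["other"] * len(events)))
        )
        flags = children.set_index("child_id")[[f"cond_{s}" for s in BODY_SYSTEMS]]
        flags.columns = BODY_SYSTEMS
        res = descriptive.subgroup_summary(
            children, flags, ("pulmonary_respiratory",), courses
        )
        assert res.mean_flagged == pytest.approx(res.mean_unflagged, rel=0.10)
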