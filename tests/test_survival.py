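import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dectresp._util import MONTH_DAYS
from dectresp.cohort import ClassificationResult, ResponseCategory
from dectresp.errors import EvaluabilityError
from dectresp.survival import (
    SurvivalRecord,
    compare_groups,
    concordance,
    derive_pfs,
    hazard_ratio,
    km_curve,
    logrank_test,
    reclassify_nonresponders,
    responder_percentage,
)

from conftest import day, make_course
from oracles import oracle_logrank_chi2, oracle_permutation_p


def rec(t, event=True, responder=True, pid=None, criterion="DECT"):
    return SurvivalRecord(
        patient_id=pid or f"p{t}",
        criterion=criterion,
        time_months=float(t),
        event=event,
        responder=responder,
    )


def cls_result(pid, category, criterion="DECT", when=91, responder=None):
    return ClassificationResult(
        patient_id=pid,
        criterion=criterion,
        category=ResponseCategory(category),
        responder=responder,
        assessment_date=day(when),
    )


class TestDerivePfs:
    def test_progression_day_152(self):
        course = make_course(lesion_specs={"L1": {0: (20,), 91: (19,)}})
        results = [cls_result("P1", "SD", when=91), cls_result("P1", "PD", when=152)]
        r = derive_pfs(course, course.treatment_lines[0], results)
        assert r.event
        assert r.time_months == pytest.approx(152 / MONTH_DAYS)  # 4.99 months
        assert round(r.time_months, 2) == 4.99

    def test_censored_at_followup_day_300(self):
        course = make_course(last_followup_day=300)
        results = [cls_result("P1", "SD", when=91)]
        r = derive_pfs(course, course.treatment_lines[0], results, death_is_event=False)
        assert not r.event
        assert round(r.time_months, 2) == 9.86

    def test_progression_on_start_date(self):
        course = make_course()
        results = [cls_result("P1", "PD", when=0)]
        r = derive_pfs(course, course.treatment_lines[0], results)
        assert r.event and r.time_months == 0.0

    def test_death_counts_as_event_by_default(self):
        course = make_course(death_day=200, last_followup_day=200)
        results = [cls_result("P1", "SD", when=91)]
        r = derive_pfs(course, course.treatment_lines[0], results)
        assert r.event and r.time_months == pytest.approx(200 / MONTH_DAYS)
        r2 = derive_pfs(
            course, course.treatment_lines[0], results, death_is_event=False
        )
        assert not r2.event

    def test_censoring_at_next_line_start(self):
        course = make_course(line_days=((0, 150), (200, None)), last_followup_day=400)
        results = [cls_result("P1", "SD", when=91)]
        r = derive_pfs(course, course.treatment_lines[0], results, death_is_event=False)
        assert not r.event and r.time_months == pytest.approx(200 / MONTH_DAYS)

    @settings(max_examples=40, deadline=None)
    @given(fu_day=st.integers(100, 1000))
    def test_censor_time_bounded_by_followup(self, fu_day):
        course = make_course(last_followup_day=fu_day)
        results = [cls_result("P1", "SD", when=91)]
        r = derive_pfs(course, course.treatment_lines[0], results)
        assert r.time_months <= fu_day / MONTH_DAYS + 1e-12


class TestReclassify:
    def test_therapy_change_within_window_overrides(self):
        course = make_course(therapy_change_days=(181,))
        (r,) = reclassify_nonresponders([cls_result("P1", "SD", when=91)], course)
        assert r.responder is False
        assert r.category is ResponseCategory.SD  # category unchanged
        assert "override" in r.detail

    def test_death_beyond_window_unchanged(self):
        course = make_course(death_day=291 + 10, last_followup_day=301)
        # death 210 days after the day-91 assessment: outside 182-day window
        (r,) = reclassify_nonresponders([cls_result("P1", "PR", when=91)], course)
        assert r.responder is True

    def test_no_outcome_events_identity(self):
        course = make_course()
        results = [cls_result("P1", "PR", when=91)]
        assert reclassify_nonresponders(results, course) == results

    def test_pd_untouched(self):
        course = make_course(therapy_change_days=(100,))
        (r,) = reclassify_nonresponders([cls_result("P1", "PD", when=91)], course)
        assert r.responder is False and "override" not in r.detail


class TestKm:
    def test_median_all_events(self):
        curve = km_curve([rec(t) for t in (1, 2, 3, 4, 5)])
        assert curve.median == 3.0

    def test_single_event(self):
        assert km_curve([rec(7.5)]).median == 7.5

    def test_all_censored_median_undefined(self):
        curve = km_curve([rec(t, event=False) for t in (1, 2, 3)])
        assert curve.median is None

    def test_no_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 2.0, 3.0, 5.0]
        curve = km_curve([rec(t) for t in times])
        n = len(times)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(sum(ti > t for ti in times) / n)

    def test_empty_errors(self):
        with pytest.raises(EvaluabilityError):
            km_curve([])


class TestLogrank:
    def test_identical_groups_null(self):
        g = [rec(t) for t in (1, 2, 3, 4, 5)]
        chi2, p = logrank_test(g, list(g))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        a = [rec(t + 30) for t in rng.exponential(5, 20)]
        b = [rec(t) for t in rng.exponential(5, 20)]
        _, p = logrank_test(a, b)
        assert p < 0.001

    def test_statistic_matches_textbook_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            na = int(rng.integers(2, n - 1))
            times = rng.exponential(5, n).round(2)
            events = rng.random(n) < 0.8
            a = [rec(times[i], bool(events[i])) for i in range(na)]
            b = [rec(times[i], bool(events[i])) for i in range(na, n)]
            chi2_oracle = oracle_logrank_chi2(
                times[:na], events[:na], times[na:], events[na:]
            )
            if chi2_oracle == 0.0:
                continue
            chi2, _ = logrank_test(a, b)
            assert chi2 == pytest.approx(chi2_oracle, abs=1e-8)

    def test_permutation_p_matches_oracle_exhaustively(self):
        # permute labels through the package statistic; the exact p must equal
        # the oracle's exhaustive permutation p
        rng = np.random.default_rng(7)
        for _ in range(4):
            n, na = 7, 3
            times = rng.exponential(5, n).round(2).tolist()
            events = (rng.random(n) < 0.85).tolist()

            def package_chi2(a_idx):
                a = [rec(times[i], events[i]) for i in a_idx]
                b = [rec(times[i], events[i]) for i in range(n) if i not in a_idx]
                return logrank_test(a, b)[0]

            observed = package_chi2(set(range(na)))
            perms = [set(c) for c in itertools.combinations(range(n), na)]
            p_pkg = sum(package_chi2(s) >= observed - 1e-12 for s in perms) / len(perms)
            _, p_oracle = oracle_permutation_p(times, events, na)
            assert p_pkg == pytest.approx(p_oracle, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 100), seed=st.integers(0, 10**5))
    def test_time_rescaling_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        a = [rec(t, bool(e)) for t, e in zip(rng.exponential(5, 8), rng.random(8) < 0.8)]
        b = [rec(t, bool(e)) for t, e in zip(rng.exponential(8, 8), rng.random(8) < 0.8)]
        chi2_1, _ = logrank_test(a, b)
        a2 = [rec(r.time_months * scale, r.event) for r in a]
        b2 = [rec(r.time_months * scale, r.event) for r in b]
        chi2_2, _ = logrank_test(a2, b2)
        assert chi2_1 == pytest.approx(chi2_2, rel=1e-9)


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        g = [rec(t) for t in (1, 2, 3, 4, 5)]
        assert hazard_ratio(g, list(g)).hr == pytest.approx(1.0)

    def test_simulated_true_half(self):
        rng = np.random.default_rng(21)
        a = [rec(t) for t in rng.exponential(10, 500)]
        b = [rec(t, responder=False) for t in rng.exponential(5, 500)]
        hr = hazard_ratio(a, b)
        assert 0.4 <= hr.hr <= 0.62
        assert hr.ci_low < hr.hr < hr.ci_high

    def test_label_swap_inverts(self):
        rng = np.random.default_rng(22)
        a = [rec(t) for t in rng.exponential(10, 60)]
        b = [rec(t) for t in rng.exponential(5, 60)]
        assert hazard_ratio(a, b).hr == pytest.approx(1 / hazard_ratio(b, a).hr)

    def test_zero_events_flagged_unbounded(self):
        a = [rec(t, event=False) for t in (1, 2, 3)]
        b = [rec(t) for t in (1, 2, 3)]
        with pytest.warns(UserWarning, match="unbounded"):
            hr = hazard_ratio(a, b)
        assert hr.unbounded and hr.hr == 0.0

    def test_cox_mode_agrees_roughly(self):
        rng = np.random.default_rng(23)
        a = [rec(t) for t in rng.exponential(10, 200)]
        b = [rec(t) for t in rng.exponential(5, 200)]
        mh = hazard_ratio(a, b).hr
        cox = hazard_ratio(a, b, method="cox").hr
        assert cox == pytest.approx(mh, rel=0.25)


class TestConcordance:
    def test_pd_agreement_9_of_11(self):
        a = [cls_result(f"p{i}", "PD") for i in range(11)]
        b = [
            cls_result(f"p{i}", "PD" if i < 9 else "SD", criterion="CA125")
            for i in range(11)
        ]
        table = concordance(a, b)
        assert table.n == 11
        assert table.agreement_percent("PD", "PD") == 82

    def test_pr_agreement_5_of_8(self):
        a = [cls_result(f"p{i}", "PR") for i in range(8)]
        b = [
            cls_result(f"p{i}", "PR" if i < 5 else "SD", criterion="RECIST")
            for i in range(8)
        ]
        assert concordance(a, b).agreement_percent("PR", "PR") == 63

    def test_identical_streams_diagonal(self):
        cats = ["PR", "SD", "PD", "SD"]
        a = [cls_result(f"p{i}", c) for i, c in enumerate(cats)]
        table = concordance(a, list(a))
        assert table.overall_agreement_percent == 100
        assert all(r == c for r, c in table.counts)

    def test_ne_not_jointly_evaluable(self):
        a = [cls_result("p0", "PR"), cls_result("p1", "NE")]
        b = [cls_result("p0", "PR"), cls_result("p1", "PD")]
        assert concordance(a, b).n == 1

    def test_disjoint_sets_warn_empty(self):
        a = [cls_result("x", "PR")]
        b = [cls_result("y", "PR")]
        with pytest.warns(UserWarning, match="disjoint"):
            table = concordance(a, b)
        assert table.n == 0


class TestAggregation:
    def test_responder_percentage_25_of_32(self):
        results = [cls_result(f"p{i}", "SD" if i < 25 else "PD") for i in range(32)]
        assert responder_percentage(results) == 78

    def test_half_away_rounding(self):
        # 5/8 = 62.5 -> 63
        results = [cls_result(f"p{i}", "SD" if i < 5 else "PD") for i in range(8)]
        assert responder_percentage(results) == 63

    def test_compare_groups_summary(self):
        rng = np.random.default_rng(31)
        records = [rec(t, pid=f"a{i}") for i, t in enumerate(rng.exponential(10, 30))]
        records += [
            rec(t, responder=False, pid=f"b{i}")
            for i, t in enumerate(rng.exponential(4, 30))
        ]
        cmp = compare_groups(records)
        assert cmp.n_responders == 30 and cmp.n_nonresponders == 30
        assert cmp.hr < 1
        assert 0 <= cmp.p_value <= 1
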