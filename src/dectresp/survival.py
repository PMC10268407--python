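"""Per-criterion progression-free survival and group comparison.

Derives PFS records from classification streams, applies the outcome-based
non-responder override (therapy change or death within 6 months of the
follow-up examination), and compares responder vs non-responder survival with
Kaplan-Meier curves, the log-rank test and a Mantel-Haenszel hazard ratio.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from math import exp, log, sqrt
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from ._util import days_to_months, round_half_away
from .cohort import (
    ClassificationResult,
    PatientCourse,
    ResponseCategory,
    TreatmentLine,
)
from .errors import DomainError, EvaluabilityError

#: "within 6 months" fixed at 182 days for determinism.
NONRESPONDER_WINDOW_DAYS = 182


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    criterion: str
    time_months: float
    event: bool
    responder: bool

    def __post_init__(self):
        if self.time_months < 0:
            raise DomainError(f"time_months must be >= 0, got {self.time_months}")


def derive_pfs(
    course: PatientCourse,
    line: TreatmentLine,
    results: Sequence[ClassificationResult],
    progression_date: Optional[dt.date] = None,
    responder: Optional[bool] = None,
    death_is_event: bool = True,
) -> SurvivalRecord:
    """PFS for one treatment line under one criterion.

    The event time is the first PD classification in ``results`` (or the
    explicit ``progression_date`` override, whichever is given); absent
    progression, death counts as an event when ``death_is_event``, otherwise
    the record is censored at the earliest of last follow-up, death and the
    next line start.  ``responder`` defaults to the final non-NE
    classification's responder flag.
    """
    start = line.start_date
    if progression_date is None:
        pd_dates = [
            r.assessment_date
            for r in results
            if r.category is ResponseCategory.PD and r.assessment_date >= start
        ]
        progression_date = min(pd_dates) if pd_dates else None

    bounds = [course.last_followup_date]
    if course.death_date is not None:
        bounds.append(course.death_date)
    nxt = course.next_line_start(line)
    if nxt is not None:
        bounds.append(nxt)
    censor_date = min(bounds)

    if responder is None:
        evaluable = [r for r in results if r.category is not ResponseCategory.NE]
        if not evaluable:
            raise EvaluabilityError(
                f"no evaluable classification for patient {course.patient_id}"
            )
        responder = bool(evaluable[-1].responder)

    if progression_date is not None and progression_date <= censor_date:
        time_days = (progression_date - start).days
        event = True
    elif (
        death_is_event
        and course.death_date is not None
        and course.death_date <= censor_date
    ):
        time_days = (course.death_date - start).days
        event = True
    else:
        time_days = (censor_date - start).days
        event = False
    criterion = results[0].criterion if results else "RECIST"
    return SurvivalRecord(
        patient_id=course.patient_id,
        criterion=criterion,
        time_months=days_to_months(max(time_days, 0)),
        event=event,
        responder=responder,
    )


def reclassify_nonresponders(
    results: Iterable[ClassificationResult],
    course: PatientCourse,
    window_days: int = NONRESPONDER_WINDOW_DAYS,
) -> list[ClassificationResult]:
    """Force responder = False when a therapy change or death follows the
    follow-up examination within ``window_days``; category is unchanged and the
    override is recorded in ``detail``."""
    out = []
    outcome_dates = list(course.therapy_change_dates)
    if course.death_date is not None:
        outcome_dates.append(course.death_date)
    for r in results:
        if r.responder:
            hits = [
                d
                for d in outcome_dates
                if 0 <= (d - r.assessment_date).days <= window_days
            ]
            if hits:
                kind = (
                    "death"
                    if course.death_date is not None and min(hits) == course.death_date
                    else "therapy change"
                )
                r = r.model_copy(
                    update={
                        "responder": False,
                        "detail": (
                            r.detail
                            + f"; non-responder override: {kind} at {min(hits)} "
                            f"within {window_days} d of follow-up"
                        ).lstrip("; "),
                    }
                )
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / hazard ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KmCurve:
    times: tuple[float, ...]
    survival: tuple[float, ...]
    median: Optional[float]


def km_curve(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Product-limit estimate; median = smallest t with S(t) <= 0.5."""
    if not records:
        raise EvaluabilityError("km_curve requires at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(
        [r.time_months for r in records],
        event_observed=[r.event for r in records],
    )
    sf = kmf.survival_function_
    median = kmf.median_survival_time_
    if not np.isfinite(median):
        median = None
    else:
        median = float(median)
    return KmCurve(
        times=tuple(float(t) for t in sf.index),
        survival=tuple(float(v) for v in sf.iloc[:, 0]),
        median=median,
    )


def _risk_table(group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]):
    """Per-event-time (n_a, d_a, n_b, d_b, E_a, V) from the pooled sample."""
    ta = np.array([r.time_months for r in group_a])
    ea = np.array([r.event for r in group_a], dtype=bool)
    tb = np.array([r.time_months for r in group_b])
    eb = np.array([r.event for r in group_b], dtype=bool)
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O_a = E_a = O_b = E_b = V = 0.0
    for t in event_times:
        na = float((ta >= t).sum())
        nb = float((tb >= t).sum())
        da = float(((ta == t) & ea).sum())
        db = float(((tb == t) & eb).sum())
        n, d = na + nb, da + db
        if n == 0 or d == 0:
            continue
        O_a += da
        O_b += db
        E_a += na * d / n
        E_b += nb * d / n
        if n > 1:
            V += na * nb * d * (n - d) / (n * n * (n - 1))
    return O_a, E_a, O_b, E_b, V


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test (ties via hypergeometric variance).

    Returns ``(chi-square statistic, p-value)``.  Degenerate inputs (no events
    or no at-risk overlap) return ``(0.0, 1.0)`` with a warning.
    """
    if not group_a or not group_b:
        raise EvaluabilityError("both groups must be non-empty")
    O_a, E_a, O_b, E_b, V = _risk_table(group_a, group_b)
    if V == 0:
        warnings.warn("degenerate log-rank comparison (no variance); p = 1")
        return 0.0, 1.0
    res = _ll_logrank(
        [r.time_months for r in group_a],
        [r.time_months for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    method: str
    unbounded: bool = False


def hazard_ratio(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
    method: Literal["mantel-haenszel", "cox"] = "mantel-haenszel",
    alpha: float = 0.05,
) -> HazardRatioResult:
    """Hazard of group_a relative to group_b.

    Default is the Mantel-Haenszel O/E ratio from the log-rank risk table with
    a log-normal CI (the estimator common survival software prints); ``cox``
    switches to the Cox partial-likelihood estimate.
    """
    if not group_a or not group_b:
        raise EvaluabilityError("both groups must be non-empty")
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    if method == "cox":
        import pandas as pd

        df = pd.DataFrame(
            {
                "t": [r.time_months for r in group_a] + [r.time_months for r in group_b],
                "e": [r.event for r in group_a] + [r.event for r in group_b],
                "g": [1] * len(group_a) + [0] * len(group_b),
            }
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        hr = float(np.exp(cph.params_["g"]))
        lo, hi = np.exp(cph.confidence_intervals_.loc["g"])
        return HazardRatioResult(hr, float(lo), float(hi), "cox")
    if method != "mantel-haenszel":
        raise ValueError(f"unknown method {method!r}")
    O_a, E_a, O_b, E_b, _ = _risk_table(group_a, group_b)
    if O_a == 0 or O_b == 0:
        warnings.warn("zero events in a group; hazard-ratio CI unbounded")
        hr = 0.0 if O_a == 0 and O_b > 0 else float("inf")
        if O_a == 0 and O_b == 0:
            hr = float("nan")
        return HazardRatioResult(hr, 0.0, float("inf"), "mantel-haenszel", True)
    hr = (O_a / E_a) / (O_b / E_b)
    se = sqrt(1.0 / E_a + 1.0 / E_b)
    return HazardRatioResult(
        hr=hr,
        ci_low=exp(log(hr) - z * se),
        ci_high=exp(log(hr) + z * se),
        method="mantel-haenszel",
    )


# ---------------------------------------------------------------------------
# Concordance and responder aggregation
# ---------------------------------------------------------------------------

_CATEGORY_ORDER = [
    ResponseCategory.CR,
    ResponseCategory.PR,
    ResponseCategory.SD,
    ResponseCategory.PD,
]


@dataclass
class ConcordanceTable:
    row_criterion: str
    col_criterion: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def row_total(self, row_cat: ResponseCategory | str) -> int:
        row_cat = ResponseCategory(row_cat).value
        return sum(v for (r, _), v in self.counts.items() if r == row_cat)

    def agreement_percent(
        self, row_cat: ResponseCategory | str, col_cat: ResponseCategory | str
    ) -> Optional[int]:
        """Percent of row-category patients with the given column category,
        rounded half away from zero to an integer; None for an empty row."""
        row_cat = ResponseCategory(row_cat).value
        col_cat = ResponseCategory(col_cat).value
        total = self.row_total(row_cat)
        if total == 0:
            return None
        return int(round_half_away(100.0 * self.counts.get((row_cat, col_cat), 0) / total))

    @property
    def agreement_fractions(self) -> dict[tuple[str, str], int]:
        return {
            (r, c): self.agreement_percent(r, c)
            for (r, c) in self.counts
            if self.row_total(r) > 0
        }

    @property
    def overall_agreement_percent(self) -> Optional[int]:
        if self.n == 0:
            return None
        diag = sum(v for (r, c), v in self.counts.items() if r == c)
        return int(round_half_away(100.0 * diag / self.n))


def concordance(
    results_a: Sequence[ClassificationResult],
    results_b: Sequence[ClassificationResult],
) -> ConcordanceTable:
    """Cross-tabulate two criteria's categories over jointly evaluable patients.

    One result per patient per stream is expected (the per-line final
    classification); NE patients on either side are not jointly evaluable.
    """
    a_by_pid = {r.patient_id: r for r in results_a}
    b_by_pid = {r.patient_id: r for r in results_b}
    shared = set(a_by_pid) & set(b_by_pid)
    row_crit = results_a[0].criterion if results_a else "?"
    col_crit = results_b[0].criterion if results_b else "?"
    table = ConcordanceTable(row_criterion=row_crit, col_criterion=col_crit)
    if not shared:
        warnings.warn("disjoint patient sets; empty concordance table")
        return table
    for pid in shared:
        ra, rb = a_by_pid[pid], b_by_pid[pid]
        if (
            ra.category is ResponseCategory.NE
            or rb.category is ResponseCategory.NE
        ):
            continue
        key = (ra.category.value, rb.category.value)
        table.counts[key] = table.counts.get(key, 0) + 1
    return table


def responder_percentage(results: Sequence[ClassificationResult]) -> Optional[int]:
    """Percent of evaluable patients who are responders, rounded half away
    from zero to an integer; None when no patient is evaluable."""
    flags = [r.responder for r in results if r.category is not ResponseCategory.NE]
    if not flags:
        return None
    return int(round_half_away(100.0 * sum(flags) / len(flags)))


def category_percentage(
    results: Sequence[ClassificationResult], category: ResponseCategory | str
) -> Optional[int]:
    """Percent of evaluable patients in one category (half-away rounding)."""
    category = ResponseCategory(category)
    cats = [r.category for r in results if r.category is not ResponseCategory.NE]
    if not cats:
        return None
    return int(round_half_away(100.0 * sum(c is category for c in cats) / len(cats)))


# ---------------------------------------------------------------------------
# Group comparison summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    criterion: str
    n_responders: int
    n_nonresponders: int
    median_responder: Optional[float]
    median_nonresponder: Optional[float]
    chi2: float
    p_value: float
    hr: float
    ci_low: float
    ci_high: float


def compare_groups(
    records: Sequence[SurvivalRecord], hr_method: str = "mantel-haenszel"
) -> GroupComparison:
    """Responder vs non-responder KM medians, log-rank and hazard ratio."""
    resp = [r for r in records if r.responder]
    nonresp = [r for r in records if not r.responder]
    if not resp or not nonresp:
        raise EvaluabilityError("both responder groups must be non-empty")
    chi2, p = logrank_test(resp, nonresp)
    hr = hazard_ratio(resp, nonresp, method=hr_method)
    return GroupComparison(
        criterion=records[0].criterion,
        n_responders=len(resp),
        n_nonresponders=len(nonresp),
        median_responder=km_curve(resp).median,
        median_nonresponder=km_curve(nonresp).median,
        chi2=chi2,
        p_value=round(p, 4),
        hr=hr.hr,
        ci_low=hr.ci_low,
        ci_high=hr.ci_high,
    )
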