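"""Iodine-concentration response criterion for dual-energy CT follow-up.

Lesion iodine is normalised to the aortic blood pool (ratio), aggregated
across target lesions (sum by default, mirroring SLD summation), and the
percent change from baseline is classified against a symmetric threshold
(default 15%): decrease beyond it is PR, increase beyond it is PD, anything
between is SD.  Every non-PD patient is a responder; any decrease at all is
additionally surfaced via the ``any_decrease`` flag.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from ._util import percent_change
from .cohort import (
    ClassificationResult,
    LesionMeasurement,
    PatientCourse,
    ResponseCategory,
    TreatmentLine,
    imaging_window,
)
from .errors import DomainError, EvaluabilityError

DEFAULT_THRESHOLD_PERCENT = 15.0
SWEEP_THRESHOLDS = (10.0, 15.0, 20.0)

AggregateMode = Literal["sum", "mean"]


@dataclass(frozen=True)
class NormalizedIodine:
    value: float
    normalized: bool


@dataclass(frozen=True)
class DectCategory:
    value: ResponseCategory  # PR, SD or PD
    responder: bool
    percent_change: float
    any_decrease: bool


@dataclass(frozen=True)
class IodineAssessment:
    baseline_iodine: float
    followup_iodine: float
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT

    @property
    def aggregate_percent_change(self) -> float:
        return percent_change(self.baseline_iodine, self.followup_iodine)


def normalize_iodine(
    lesion_iodine: float,
    aortic_iodine: Optional[float],
    fallback_unnormalized: bool = False,
) -> NormalizedIodine:
    """Lesion iodine as a fraction of aortic iodine.

    With the fallback enabled, a missing aortic value returns the raw lesion
    concentration flagged unnormalised instead of raising.
    """
    if lesion_iodine < 0:
        raise DomainError(f"lesion iodine must be >= 0, got {lesion_iodine}")
    if aortic_iodine is None:
        if fallback_unnormalized:
            return NormalizedIodine(lesion_iodine, normalized=False)
        raise DomainError("aortic iodine missing and fallback disabled")
    if aortic_iodine <= 0:
        raise DomainError(f"aortic iodine must be > 0, got {aortic_iodine}")
    return NormalizedIodine(lesion_iodine / aortic_iodine, normalized=True)


def aggregate_iodine(
    lesions: Iterable[LesionMeasurement],
    mode: AggregateMode = "sum",
    normalized: bool = True,
    fallback_unnormalized: bool = False,
) -> float:
    """Aggregate per-lesion (normalised) iodine at one timepoint."""
    values = []
    for m in lesions:
        if m.iodine_mg_per_ml is None:
            continue
        if normalized:
            values.append(
                normalize_iodine(
                    m.iodine_mg_per_ml,
                    m.aortic_iodine_mg_per_ml,
                    fallback_unnormalized=fallback_unnormalized,
                ).value
            )
        else:
            values.append(m.iodine_mg_per_ml)
    if not values:
        raise EvaluabilityError("no iodine-bearing lesions at timepoint")
    if mode == "mean":
        return float(sum(values) / len(values))
    if mode != "sum":
        raise ValueError(f"unknown aggregate mode {mode!r}")
    return float(sum(values))


def classify_dect(
    baseline_agg: float,
    followup_agg: float,
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT,
) -> DectCategory:
    """Three-way classification of the iodine percent change.

    Inclusive boundaries: change <= -threshold is PR, >= +threshold is PD,
    otherwise SD.  Responder iff not PD.
    """
    if threshold_percent <= 0:
        raise DomainError(f"threshold must be > 0, got {threshold_percent}")
    delta = percent_change(baseline_agg, followup_agg)
    if delta >= threshold_percent:
        cat = ResponseCategory.PD
    elif delta <= -threshold_percent:
        cat = ResponseCategory.PR
    else:
        cat = ResponseCategory.SD
    return DectCategory(
        value=cat,
        responder=cat is not ResponseCategory.PD,
        percent_change=delta,
        any_decrease=delta < 0,
    )


def classify_course_dect(
    course: PatientCourse,
    line: TreatmentLine,
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT,
    mode: AggregateMode = "sum",
    normalized: bool = True,
    fallback_unnormalized: bool = False,
    baseline_window_days: int = 30,
) -> list[ClassificationResult]:
    """Classify each iodine-bearing follow-up scan against the line baseline.

    Mid-treatment scans are classified pairwise against the baseline scan; the
    per-line category is conventionally read from the LAST result.
    """
    baseline_date, followups = imaging_window(
        course,
        line,
        dates=course.iodine_dates(),
        baseline_window_days=baseline_window_days,
    )

    def _ne(reason: str, date: Optional[dt.date] = None) -> list[ClassificationResult]:
        return [
            ClassificationResult(
                patient_id=course.patient_id,
                criterion="DECT",
                category=ResponseCategory.NE,
                assessment_date=date or line.start_date,
                detail=reason,
            )
        ]

    if baseline_date is None:
        return _ne("no baseline iodine imaging for line")
    if not followups:
        return _ne("no follow-up iodine imaging for line", baseline_date)
    try:
        baseline_agg = aggregate_iodine(
            course.lesions_at(baseline_date),
            mode=mode,
            normalized=normalized,
            fallback_unnormalized=fallback_unnormalized,
        )
    except EvaluabilityError as exc:
        return _ne(str(exc), baseline_date)
    if baseline_agg <= 0:
        return _ne("baseline aggregate iodine is zero", baseline_date)

    results = []
    for date in followups:
        try:
            agg = aggregate_iodine(
                course.lesions_at(date),
                mode=mode,
                normalized=normalized,
                fallback_unnormalized=fallback_unnormalized,
            )
        except EvaluabilityError as exc:
            results.append(
                ClassificationResult(
                    patient_id=course.patient_id,
                    criterion="DECT",
                    category=ResponseCategory.NE,
                    assessment_date=date,
                    detail=str(exc),
                )
            )
            continue
        cat = classify_dect(baseline_agg, agg, threshold_percent)
        detail = f"aggregate iodine {baseline_agg:g} -> {agg:g}"
        if cat.any_decrease:
            detail += "; any-decrease responder"
        results.append(
            ClassificationResult(
                patient_id=course.patient_id,
                criterion="DECT",
                category=cat.value,
                percent_change=cat.percent_change,
                assessment_date=date,
                detail=detail,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    accuracy: float
    sensitivity_pd: float
    specificity_pd: float
    balanced_accuracy: float
    pd_calls: int
    pr_calls: int


@dataclass(frozen=True)
class SweepResult:
    metrics: tuple[ThresholdMetrics, ...]
    selected_threshold: float

    def by_threshold(self, threshold: float) -> ThresholdMetrics:
        for m in self.metrics:
            if m.threshold == threshold:
                return m
        raise KeyError(threshold)


def threshold_sweep(
    percent_changes: Sequence[float],
    reference_responder: Sequence[bool],
    thresholds: Sequence[float] = SWEEP_THRESHOLDS,
) -> SweepResult:
    """Evaluate candidate thresholds against reference responder labels.

    For each threshold every patient is re-classified (PD iff change >=
    +threshold; responder otherwise) and agreement with the reference labels is
    tabulated: accuracy, and sensitivity/specificity for detecting reference
    NON-responders as PD.  The threshold maximising balanced accuracy wins,
    ties broken toward the larger threshold.
    """
    deltas = np.asarray(percent_changes, dtype=float)
    ref = np.asarray(reference_responder, dtype=bool)
    if deltas.shape != ref.shape or deltas.ndim != 1:
        raise ValueError("percent_changes and reference labels must align 1-D")
    if deltas.size == 0:
        raise EvaluabilityError("no reference labels available for sweep")
    if not thresholds:
        raise ValueError("at least one threshold required")

    metrics = []
    for theta in thresholds:
        if theta <= 0:
            raise DomainError(f"threshold must be > 0, got {theta}")
        pred_pd = deltas >= theta
        pred_responder = ~pred_pd
        acc = float(np.mean(pred_responder == ref))
        pos = ~ref  # reference non-responders (PD) are the positive class
        sens = float(np.mean(pred_pd[pos])) if pos.any() else 1.0
        spec = float(np.mean(pred_responder[ref])) if ref.any() else 1.0
        metrics.append(
            ThresholdMetrics(
                threshold=float(theta),
                accuracy=acc,
                sensitivity_pd=sens,
                specificity_pd=spec,
                balanced_accuracy=(sens + spec) / 2.0,
                pd_calls=int(pred_pd.sum()),
                pr_calls=int((deltas <= -theta).sum()),
            )
        )
    best = max(metrics, key=lambda m: (m.balanced_accuracy, m.threshold))
    return SweepResult(metrics=tuple(metrics), selected_threshold=best.threshold)
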