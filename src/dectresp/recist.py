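"""Size-based response classification from target-lesion longest diameters.

Default thresholds classify against BASELINE only (PR at a 30% decrease, PD at
a 20% increase, inclusive boundaries); a ``strict_recist`` mode references the
nadir for PD and additionally requires a >= 5 mm absolute increase.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

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

PR_THRESHOLD = -30.0
PD_THRESHOLD = 20.0
STRICT_PD_ABSOLUTE_MM = 5.0


@dataclass(frozen=True)
class SldAssessment:
    """Baseline and follow-up sums of longest diameters for one comparison."""

    baseline_sld_mm: float
    followup_sld_mm: float
    new_lesions: bool = False

    @property
    def percent_change(self) -> float:
        """Defined only when the baseline SLD is positive."""
        return percent_change(self.baseline_sld_mm, self.followup_sld_mm)


def compute_sld(
    lesions: Iterable[LesionMeasurement],
    target_ids: Optional[set[str]] = None,
    carry_forward: bool = False,
    history: Optional[Mapping[str, float]] = None,
) -> float:
    """Sum of longest diameters at one timepoint.

    With ``target_ids`` given, every target lesion must be present at the
    timepoint; absent lesions are carried at their last observed diameter only
    when ``carry_forward`` is set (``history`` maps lesion_id to that value),
    otherwise an :class:`EvaluabilityError` is raised.  A diameter of 0 is a
    disappeared lesion, not a missing one.
    """
    present = {m.lesion_id: m.longest_diameter_mm for m in lesions}
    if target_ids is None:
        if not present:
            raise EvaluabilityError("no lesion measurements at timepoint")
        return float(sum(present.values()))
    total = 0.0
    for lid in sorted(target_ids):
        if lid in present:
            total += present[lid]
        elif carry_forward and history is not None and lid in history:
            total += history[lid]
        else:
            raise EvaluabilityError(
                f"target lesion {lid!r} missing at timepoint and carry-forward off"
            )
    if not target_ids:
        raise EvaluabilityError("no lesion measurements at timepoint")
    return float(total)


def classify_recist(
    assessment: SldAssessment,
    pr_threshold: float = PR_THRESHOLD,
    pd_threshold: float = PD_THRESHOLD,
    strict_recist: bool = False,
    nadir_sld_mm: Optional[float] = None,
) -> ResponseCategory:
    """Classify one SLD comparison into CR/PR/SD/PD.

    New lesions force PD.  A follow-up SLD of 0 without new lesions is CR.
    In strict mode PD is referenced to the nadir SLD and requires a >= 5 mm
    absolute increase over it.
    """
    if assessment.new_lesions:
        return ResponseCategory.PD
    b, f = assessment.baseline_sld_mm, assessment.followup_sld_mm
    if b == 0 and f == 0:
        return ResponseCategory.CR
    if b <= 0:
        # reappearance after complete disappearance at baseline
        return ResponseCategory.PD
    if f == 0:
        return ResponseCategory.CR
    delta = assessment.percent_change
    if strict_recist:
        ref = nadir_sld_mm if nadir_sld_mm is not None else b
        if ref <= 0:
            raise DomainError("nadir SLD must be > 0 in strict mode")
        growth = percent_change(ref, f)
        if growth >= pd_threshold and (f - ref) >= STRICT_PD_ABSOLUTE_MM:
            return ResponseCategory.PD
        if delta <= pr_threshold:
            return ResponseCategory.PR
        return ResponseCategory.SD
    if delta >= pd_threshold:
        return ResponseCategory.PD
    if delta <= pr_threshold:
        return ResponseCategory.PR
    return ResponseCategory.SD


def classify_course_recist(
    course: PatientCourse,
    line: TreatmentLine,
    carry_forward: bool = False,
    strict_recist: bool = False,
    baseline_window_days: int = 30,
) -> list[ClassificationResult]:
    """Classify every follow-up scan of a treatment line against its baseline.

    Returns one :class:`ClassificationResult` per follow-up timepoint, ordered
    by date; an unevaluable line yields a single NE result dated at the line
    start with the reason in ``detail``.
    """
    baseline_date, followups = imaging_window(
        course, line, baseline_window_days=baseline_window_days
    )

    def _ne(reason: str, date: Optional[dt.date] = None) -> list[ClassificationResult]:
        return [
            ClassificationResult(
                patient_id=course.patient_id,
                criterion="RECIST",
                category=ResponseCategory.NE,
                assessment_date=date or line.start_date,
                detail=reason,
            )
        ]

    if baseline_date is None:
        return _ne("no baseline imaging for line")
    if not followups:
        return _ne("no follow-up imaging for line", baseline_date)

    baseline_lesions = course.lesions_at(baseline_date)
    target_ids = {m.lesion_id for m in baseline_lesions}
    baseline_sld = compute_sld(baseline_lesions)

    history: dict[str, float] = {
        m.lesion_id: m.longest_diameter_mm for m in baseline_lesions
    }
    nadir_sld = baseline_sld
    results: list[ClassificationResult] = []
    for date in followups:
        measurements = course.lesions_at(date)
        new = {m.lesion_id for m in measurements} - target_ids
        try:
            sld = compute_sld(
                measurements, target_ids, carry_forward=carry_forward, history=history
            )
        except EvaluabilityError as exc:
            results.append(
                ClassificationResult(
                    patient_id=course.patient_id,
                    criterion="RECIST",
                    category=ResponseCategory.NE,
                    assessment_date=date,
                    detail=str(exc),
                )
            )
            continue
        assessment = SldAssessment(
            baseline_sld_mm=baseline_sld,
            followup_sld_mm=sld,
            new_lesions=bool(new),
        )
        category = classify_recist(
            assessment, strict_recist=strict_recist, nadir_sld_mm=nadir_sld
        )
        delta = assessment.percent_change if baseline_sld > 0 else None
        detail = f"SLD {baseline_sld:g} -> {sld:g} mm"
        if new:
            detail += f"; new lesions: {', '.join(sorted(new))}"
        results.append(
            ClassificationResult(
                patient_id=course.patient_id,
                criterion="RECIST",
                category=category,
                percent_change=delta,
                assessment_date=date,
                detail=detail,
            )
        )
        nadir_sld = min(nadir_sld, sld)
        for m in measurements:
            history[m.lesion_id] = m.longest_diameter_mm
    return results
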