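"""GCIG-style CA125 response and progression rules.

Eligibility requires a pre-treatment value at least twice the assay ULN.
Response is a confirmed 50% fall maintained >= 28 days; progression is a rise
to at least twice the reference (nadir, or ULN for patients whose marker
normalised) confirmed by a second sample >= 7 days later.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort import (
    CA125Sample,
    ClassificationResult,
    PatientCourse,
    ResponseCategory,
    TreatmentLine,
)

RESPONSE_FACTOR = 0.5
RESPONSE_CONFIRM_DAYS = 28
PROGRESSION_FACTOR = 2.0
PROGRESSION_CONFIRM_DAYS = 7
DEFAULT_PRETREATMENT_WINDOW_DAYS = 14
DEFAULT_MIN_FOLLOWUP_DAYS = 28


@dataclass(frozen=True)
class Ca125Eligibility:
    evaluable: bool
    pretreatment_value: Optional[float] = None
    pretreatment_date: Optional[dt.date] = None
    reason: str = ""


@dataclass(frozen=True)
class Ca125Assessment:
    """Summary of one line's CA125 evaluation."""

    pretreatment_value: float
    uln: float
    nadir_value: float
    response_confirm_date: Optional[dt.date] = None
    progression_date: Optional[dt.date] = None
    evaluable: bool = True


def ca125_eligibility(
    series: Sequence[CA125Sample],
    treatment_start: dt.date,
    uln: float,
    window_days: Optional[int] = DEFAULT_PRETREATMENT_WINDOW_DAYS,
) -> Ca125Eligibility:
    """Locate the pre-treatment sample and apply the 2x-ULN gate.

    The pre-treatment sample is the latest sample on or before
    ``treatment_start`` and, when ``window_days`` is not None, no more than
    that many days before it.
    """
    pre = [s for s in series if s.sample_date <= treatment_start]
    if window_days is not None:
        lo = treatment_start - dt.timedelta(days=window_days)
        pre = [s for s in pre if s.sample_date >= lo]
    if not pre:
        return Ca125Eligibility(False, reason="no pre-treatment CA125 sample")
    sample = max(pre, key=lambda s: s.sample_date)
    if sample.value_u_per_ml >= 2.0 * uln:
        return Ca125Eligibility(True, sample.value_u_per_ml, sample.sample_date)
    return Ca125Eligibility(
        False,
        sample.value_u_per_ml,
        sample.sample_date,
        reason=(
            f"pre-treatment CA125 {sample.value_u_per_ml:g} < 2 x ULN ({2 * uln:g})"
        ),
    )


def ca125_response(
    series: Sequence[CA125Sample],
    treatment_start: dt.date,
    uln: float,
    window_days: Optional[int] = DEFAULT_PRETREATMENT_WINDOW_DAYS,
) -> tuple[bool, Optional[dt.date]]:
    """Confirmed 50% reduction from the pre-treatment sample.

    Responded iff some post-treatment sample s1 has value <= 0.5 x
    pretreatment AND a later sample s2 (>= 28 days after s1, value <= 0.5 x
    pretreatment) exists with no intervening sample above the 50% level.
    Returns ``(responded, date of the earliest qualifying s1)``.
    """
    elig = ca125_eligibility(series, treatment_start, uln, window_days)
    if not elig.evaluable:
        return False, None
    level = RESPONSE_FACTOR * elig.pretreatment_value
    post = sorted(
        (s for s in series if s.sample_date > treatment_start),
        key=lambda s: s.sample_date,
    )
    for i, s1 in enumerate(post):
        if s1.value_u_per_ml > level:
            continue
        for s2 in post[i + 1 :]:
            if s2.value_u_per_ml > level:
                break  # breach before any would-be confirmation
            if (s2.sample_date - s1.sample_date).days >= RESPONSE_CONFIRM_DAYS:
                return True, s1.sample_date
    return False, None


def ca125_progression(
    series: Sequence[CA125Sample],
    treatment_start: dt.date,
    uln: float,
    window_days: Optional[int] = DEFAULT_PRETREATMENT_WINDOW_DAYS,
) -> tuple[bool, Optional[dt.date]]:
    """Confirmed rise to twice the nadir (or ULN if the marker normalised).

    The running nadir starts at the pre-treatment value (when one exists) and
    is the minimum over samples up to the candidate.  The threshold is frozen
    at the first qualifying sample; the confirming sample must reach the same
    threshold >= 7 days later.  Progression date is the FIRST of the pair.
    """
    elig = ca125_eligibility(series, treatment_start, uln, window_days)
    post = sorted(
        (s for s in series if s.sample_date > treatment_start),
        key=lambda s: s.sample_date,
    )
    if len(post) < 2:
        return False, None
    nadir = elig.pretreatment_value if elig.pretreatment_value is not None else None
    for i, s1 in enumerate(post):
        nadir = s1.value_u_per_ml if nadir is None else min(nadir, s1.value_u_per_ml)
        reference = uln if nadir <= uln else nadir
        threshold = PROGRESSION_FACTOR * reference
        if s1.value_u_per_ml < threshold:
            continue
        for s2 in post[i + 1 :]:
            if (
                (s2.sample_date - s1.sample_date).days >= PROGRESSION_CONFIRM_DAYS
                and s2.value_u_per_ml >= threshold
            ):
                return True, s1.sample_date
    return False, None


def nadir_after(
    series: Sequence[CA125Sample], treatment_start: dt.date, pretreatment: Optional[float]
) -> Optional[float]:
    """Running minimum on/after treatment start, seeded with the pre-treatment value."""
    vals = [s.value_u_per_ml for s in series if s.sample_date > treatment_start]
    if pretreatment is not None:
        vals.append(pretreatment)
    return min(vals) if vals else None


def classify_gcig(
    course: PatientCourse,
    line: TreatmentLine,
    window_days: Optional[int] = DEFAULT_PRETREATMENT_WINDOW_DAYS,
    min_followup_days: int = DEFAULT_MIN_FOLLOWUP_DAYS,
) -> ClassificationResult:
    """Compose eligibility, response and progression into one category.

    PD if progression fires before (or without) a response; PR for a confirmed
    response (CR is not distinguished — a normalised-marker note lands in
    ``detail``); SD when evaluable, neither rule fires, and follow-up spans at
    least ``min_followup_days``; NE otherwise.
    """
    start = line.start_date
    uln = course.uln_u_per_ml
    nxt = course.next_line_start(line)
    series = [s for s in course.ca125 if nxt is None or s.sample_date < nxt]

    elig = ca125_eligibility(series, start, uln, window_days)
    if not elig.evaluable:
        return ClassificationResult(
            patient_id=course.patient_id,
            criterion="CA125",
            category=ResponseCategory.NE,
            assessment_date=start,
            detail=elig.reason,
        )

    responded, resp_date = ca125_response(series, start, uln, window_days)
    progressed, prog_date = ca125_progression(series, start, uln, window_days)
    pre = elig.pretreatment_value

    if progressed and (not responded or prog_date <= resp_date):
        delta = 100.0 * (
            _value_at(series, prog_date) - pre
        ) / pre if pre else None
        return ClassificationResult(
            patient_id=course.patient_id,
            criterion="CA125",
            category=ResponseCategory.PD,
            percent_change=delta,
            assessment_date=prog_date,
            detail=f"progression confirmed from {prog_date}",
        )
    if responded:
        nadir = nadir_after(series, start, pre)
        normalised = nadir is not None and nadir <= uln
        detail = f"confirmed 50% reduction from {resp_date}"
        if normalised:
            detail += "; CA125 normalised (CR-equivalent, reported as PR)"
        if progressed:
            detail += f"; later progression {prog_date}"
        delta = 100.0 * (_value_at(series, resp_date) - pre) / pre
        return ClassificationResult(
            patient_id=course.patient_id,
            criterion="CA125",
            category=ResponseCategory.PR,
            percent_change=delta,
            assessment_date=resp_date,
            detail=detail,
        )
    post = [s for s in series if s.sample_date > start]
    if post and (post[-1].sample_date - start).days >= min_followup_days:
        delta = 100.0 * (post[-1].value_u_per_ml - pre) / pre
        return ClassificationResult(
            patient_id=course.patient_id,
            criterion="CA125",
            category=ResponseCategory.SD,
            percent_change=delta,
            assessment_date=post[-1].sample_date,
            detail="neither response nor progression",
        )
    return ClassificationResult(
        patient_id=course.patient_id,
        criterion="CA125",
        category=ResponseCategory.NE,
        assessment_date=post[-1].sample_date if post else start,
        detail="insufficient follow-up",
    )


def _value_at(series: Sequence[CA125Sample], date: dt.date) -> float:
    for s in series:
        if s.sample_date == date:
            return s.value_u_per_ml
    raise KeyError(date)
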