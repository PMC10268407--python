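"""Domain types for longitudinal patient courses and cohort interchange IO.

The cohort is exchanged either as a CSV bundle (four tables in a directory:
``patients.csv``, ``lesions.csv``, ``ca125.csv``, ``treatment_lines.csv``) or
as a single JSON document.  All dates are ISO-8601 calendar dates; diameters
are stored in millimetres internally (a ``diameter_units`` flag on ingestion
accepts centimetres and converts).
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import IntegrityError, RowError, SchemaError


class LesionMeasurement(BaseModel):
    """One target lesion observed at one imaging timepoint."""

    model_config = ConfigDict(frozen=True)

    lesion_id: str
    timepoint_date: dt.date
    longest_diameter_mm: float = Field(ge=0)
    iodine_mg_per_ml: Optional[float] = Field(default=None, ge=0)
    aortic_iodine_mg_per_ml: Optional[float] = Field(default=None, gt=0)
    location: str = ""


class CA125Sample(BaseModel):
    model_config = ConfigDict(frozen=True)

    sample_date: dt.date
    value_u_per_ml: float = Field(gt=0)


class TreatmentLine(BaseModel):
    model_config = ConfigDict(frozen=True)

    line_index: int = Field(ge=0)
    start_date: dt.date
    end_date: Optional[dt.date] = None

    @model_validator(mode="after")
    def _check_span(self):
        if self.end_date is not None and self.end_date < self.start_date:
            raise ValueError("end_date precedes start_date")
        return self


#: Default CA125 upper limit of normal (U/mL) when a patient record does not
#: specify its assay's value.  Configurable per patient; a common assay ULN.
DEFAULT_ULN_U_PER_ML = 35.0


class PatientCourse(BaseModel):
    """Full longitudinal record for one patient."""

    patient_id: str
    uln_u_per_ml: float = Field(default=DEFAULT_ULN_U_PER_ML, gt=0)
    setting: Literal["first_line", "relapse"] = "relapse"
    lesions: list[LesionMeasurement] = Field(default_factory=list)
    ca125: list[CA125Sample] = Field(default_factory=list)
    treatment_lines: list[TreatmentLine] = Field(default_factory=list)
    death_date: Optional[dt.date] = None
    therapy_change_dates: list[dt.date] = Field(default_factory=list)
    last_followup_date: dt.date

    @model_validator(mode="after")
    def _validate(self):
        # CA125 samples strictly ordered by date after ingestion.
        self.ca125.sort(key=lambda s: s.sample_date)
        for a, b in zip(self.ca125, self.ca125[1:]):
            if a.sample_date == b.sample_date:
                raise ValueError(
                    f"duplicate CA125 sample date {a.sample_date} "
                    f"for patient {self.patient_id}"
                )
        self.therapy_change_dates.sort()
        # Treatment lines ordered by start, non-overlapping.
        self.treatment_lines.sort(key=lambda t: t.start_date)
        for a, b in zip(self.treatment_lines, self.treatment_lines[1:]):
            if a.end_date is not None and b.start_date < a.end_date:
                raise ValueError(
                    f"overlapping treatment lines for patient {self.patient_id}"
                )
        horizon = self.last_followup_date
        if self.death_date is not None:
            horizon = min(horizon, self.death_date)
        for m in self.lesions:
            if m.timepoint_date > horizon:
                raise ValueError(
                    f"lesion measurement {m.lesion_id}@{m.timepoint_date} after "
                    f"follow-up/death horizon for patient {self.patient_id}"
                )
        for s in self.ca125:
            if s.sample_date > horizon:
                raise ValueError(
                    f"CA125 sample at {s.sample_date} after horizon "
                    f"for patient {self.patient_id}"
                )
        seen = set()
        for m in self.lesions:
            key = (m.lesion_id, m.timepoint_date)
            if key in seen:
                raise ValueError(
                    f"duplicate lesion measurement {key} for patient "
                    f"{self.patient_id}"
                )
            seen.add(key)
        self.lesions.sort(key=lambda m: (m.timepoint_date, m.lesion_id))
        return self

    # -- convenience views ------------------------------------------------

    def imaging_dates(self) -> list[dt.date]:
        """Sorted distinct dates with any lesion measurement."""
        return sorted({m.timepoint_date for m in self.lesions})

    def iodine_dates(self) -> list[dt.date]:
        """Sorted distinct dates with at least one iodine-bearing lesion."""
        return sorted(
            {m.timepoint_date for m in self.lesions if m.iodine_mg_per_ml is not None}
        )

    @property
    def dect_evaluable(self) -> bool:
        """At least two imaging timepoints carrying iodine values."""
        return len(self.iodine_dates()) >= 2

    def lesions_at(self, date: dt.date) -> list[LesionMeasurement]:
        return [m for m in self.lesions if m.timepoint_date == date]

    def next_line_start(self, line: TreatmentLine) -> Optional[dt.date]:
        later = [
            t.start_date
            for t in self.treatment_lines
            if t.start_date > line.start_date
        ]
        return min(later) if later else None


class ResponseCategory(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NE = "NE"


RESPONDER_CATEGORIES = frozenset(
    {ResponseCategory.CR, ResponseCategory.PR, ResponseCategory.SD}
)

Criterion = Literal["RECIST", "DECT", "CA125"]


class ClassificationResult(BaseModel):
    patient_id: str
    criterion: Criterion
    category: ResponseCategory
    percent_change: Optional[float] = None
    responder: Optional[bool] = None
    assessment_date: dt.date
    detail: str = ""

    @model_validator(mode="after")
    def _responder_consistent(self):
        if self.category is ResponseCategory.NE:
            if self.responder is not None:
                raise ValueError("responder must be absent for NE results")
        else:
            expected = self.category in RESPONDER_CATEGORIES
            if self.responder is None:
                self.responder = expected
            elif self.responder and not expected:
                raise ValueError(
                    f"responder=True inconsistent with category {self.category.value}"
                )
            # responder=False with a CR/PR/SD category is permitted: it records
            # the outcome-based non-responder override (category unchanged).
        return self


# ---------------------------------------------------------------------------
# Imaging windows (shared by the RECIST and DECT engines)
# ---------------------------------------------------------------------------


def imaging_window(
    course: PatientCourse,
    line: TreatmentLine,
    dates: Optional[Sequence[dt.date]] = None,
    baseline_window_days: int = 30,
) -> tuple[Optional[dt.date], list[dt.date]]:
    """Baseline and follow-up imaging dates attributable to one line.

    A date belongs to the line if it falls in
    ``[start - baseline_window_days, next line start)``.  The earliest such
    date at or before ``start + baseline_window_days`` is the baseline; all
    later dates are follow-ups.  Returns ``(None, [])`` when no baseline scan
    exists.
    """
    if dates is None:
        dates = course.imaging_dates()
    nxt = course.next_line_start(line)
    lo = line.start_date - dt.timedelta(days=baseline_window_days)
    in_line = [d for d in dates if d >= lo and (nxt is None or d < nxt)]
    if not in_line:
        return None, []
    baseline = in_line[0]
    if baseline > line.start_date + dt.timedelta(days=baseline_window_days):
        return None, []
    return baseline, in_line[1:]


# ---------------------------------------------------------------------------
# Eligibility filter
# ---------------------------------------------------------------------------


@dataclass
class ExclusionReport:
    counts: dict[str, int] = field(default_factory=dict)
    excluded_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())


def eligibility_filter(
    cohort: Iterable[PatientCourse],
) -> tuple[list[PatientCourse], ExclusionReport]:
    """Retain patients with >= 2 iodine-bearing imaging timepoints."""
    evaluable: list[PatientCourse] = []
    report = ExclusionReport()
    for course in cohort:
        n_iodine = len(course.iodine_dates())
        if n_iodine >= 2:
            evaluable.append(course)
        else:
            reason = (
                "single iodine imaging timepoint"
                if n_iodine == 1
                else "no iodine imaging timepoints"
            )
            report.counts[reason] = report.counts.get(reason, 0) + 1
            report.excluded_ids.setdefault(reason, []).append(course.patient_id)
    return evaluable, report


# ---------------------------------------------------------------------------
# CSV bundle / JSON readers and writers
# ---------------------------------------------------------------------------

_PATIENT_COLS = [
    "patient_id",
    "uln_u_per_ml",
    "setting",
    "death_date",
    "last_followup_date",
    "therapy_change_dates",
]
_LESION_COLS = [
    "patient_id",
    "lesion_id",
    "timepoint_date",
    "longest_diameter_mm",
    "iodine_mg_per_ml",
    "aortic_iodine_mg_per_ml",
    "location",
]
_CA125_COLS = ["patient_id", "sample_date", "value_u_per_ml"]
_LINE_COLS = ["patient_id", "line_index", "start_date", "end_date"]

_BUNDLE_FILES = {
    "patients.csv": _PATIENT_COLS,
    "lesions.csv": _LESION_COLS,
    "ca125.csv": _CA125_COLS,
    "treatment_lines.csv": _LINE_COLS,
}


def _parse_date(text: str, where: str, line_no: int, problems: list) -> Optional[dt.date]:
    text = text.strip()
    if not text:
        return None
    try:
        return dt.date.fromisoformat(text)
    except ValueError:
        problems.append((line_no, f"{where}: unparseable date {text!r}"))
        return None


def _parse_float(text: str, where: str, line_no: int, problems: list) -> Optional[float]:
    text = text.strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        problems.append((line_no, f"{where}: unparseable number {text!r}"))
        return None


def _read_table(path: Path, required: Sequence[str]) -> list[tuple[int, dict]]:
    if not path.exists():
        raise SchemaError(f"missing bundle table {path.name}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s) {', '.join(missing)}"
            )
        return [(i, row) for i, row in enumerate(reader, start=2)]


def read_cohort(
    path: str | Path,
    format: Literal["csv_bundle", "json"] = "csv_bundle",
    diameter_units: Literal["mm", "cm"] = "mm",
) -> list[PatientCourse]:
    """Read a cohort from a CSV bundle directory or a JSON document.

    Rows violating invariants are rejected with row-level diagnostics
    (:class:`~dectresp.errors.RowError` carrying line numbers); duplicate
    measurement keys raise :class:`~dectresp.errors.IntegrityError`.
    """
    path = Path(path)
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return [PatientCourse.model_validate(p) for p in doc["patients"]]
    if format != "csv_bundle":
        raise ValueError(f"unknown format {format!r}")

    scale = 10.0 if diameter_units == "cm" else 1.0
    problems: list[tuple[int, str]] = []

    patients_rows = _read_table(path / "patients.csv", _PATIENT_COLS)
    lesion_rows = _read_table(path / "lesions.csv", _LESION_COLS)
    ca125_rows = _read_table(path / "ca125.csv", _CA125_COLS)
    line_rows = _read_table(path / "treatment_lines.csv", _LINE_COLS)

    lesions: dict[str, list[LesionMeasurement]] = {}
    seen_keys: set[tuple[str, str, dt.date]] = set()
    for ln, row in lesion_rows:
        pid = row["patient_id"].strip()
        date = _parse_date(row["timepoint_date"], "lesions.timepoint_date", ln, problems)
        diam = _parse_float(
            row["longest_diameter_mm"], "lesions.longest_diameter_mm", ln, problems
        )
        if date is None or diam is None:
            if diam is None and not row["longest_diameter_mm"].strip():
                problems.append((ln, "lesions.longest_diameter_mm: required"))
            continue
        if diam < 0:
            problems.append(
                (ln, f"lesions.longest_diameter_mm: must be >= 0, got {diam}")
            )
            continue
        key = (pid, row["lesion_id"].strip(), date)
        if key in seen_keys:
            raise IntegrityError(
                f"lesions.csv line {ln}: duplicate (patient_id, lesion_id, "
                f"timepoint_date) = {key}"
            )
        seen_keys.add(key)
        iod = _parse_float(row["iodine_mg_per_ml"], "lesions.iodine_mg_per_ml", ln, problems)
        aorta = _parse_float(
            row["aortic_iodine_mg_per_ml"], "lesions.aortic_iodine_mg_per_ml", ln, problems
        )
        if iod is not None and iod < 0:
            problems.append((ln, f"lesions.iodine_mg_per_ml: must be >= 0, got {iod}"))
            continue
        if aorta is not None and aorta <= 0:
            problems.append(
                (ln, f"lesions.aortic_iodine_mg_per_ml: must be > 0, got {aorta}")
            )
            continue
        lesions.setdefault(pid, []).append(
            LesionMeasurement(
                lesion_id=key[1],
                timepoint_date=date,
                longest_diameter_mm=diam * scale,
                iodine_mg_per_ml=iod,
                aortic_iodine_mg_per_ml=aorta,
                location=row.get("location", "") or "",
            )
        )

    ca125: dict[str, list[CA125Sample]] = {}
    for ln, row in ca125_rows:
        pid = row["patient_id"].strip()
        date = _parse_date(row["sample_date"], "ca125.sample_date", ln, problems)
        val = _parse_float(row["value_u_per_ml"], "ca125.value_u_per_ml", ln, problems)
        if date is None or val is None:
            continue
        if val <= 0:
            problems.append((ln, f"ca125.value_u_per_ml: must be > 0, got {val}"))
            continue
        ca125.setdefault(pid, []).append(CA125Sample(sample_date=date, value_u_per_ml=val))

    tlines: dict[str, list[TreatmentLine]] = {}
    for ln, row in line_rows:
        pid = row["patient_id"].strip()
        start = _parse_date(row["start_date"], "treatment_lines.start_date", ln, problems)
        end = _parse_date(row["end_date"], "treatment_lines.end_date", ln, problems)
        if start is None:
            problems.append((ln, "treatment_lines.start_date: required"))
            continue
        try:
            idx = int(row["line_index"])
        except ValueError:
            problems.append(
                (ln, f"treatment_lines.line_index: not an integer {row['line_index']!r}")
            )
            continue
        tlines.setdefault(pid, []).append(
            TreatmentLine(line_index=idx, start_date=start, end_date=end)
        )

    courses: list[PatientCourse] = []
    for ln, row in patients_rows:
        pid = row["patient_id"].strip()
        last_fu = _parse_date(
            row["last_followup_date"], "patients.last_followup_date", ln, problems
        )
        if last_fu is None:
            problems.append((ln, "patients.last_followup_date: required"))
            continue
        death = _parse_date(row["death_date"], "patients.death_date", ln, problems)
        uln = _parse_float(row["uln_u_per_ml"], "patients.uln_u_per_ml", ln, problems)
        changes = []
        bad = False
        for part in (row["therapy_change_dates"] or "").split(";"):
            if part.strip():
                d = _parse_date(part, "patients.therapy_change_dates", ln, problems)
                if d is None:
                    bad = True
                else:
                    changes.append(d)
        if bad:
            continue
        try:
            courses.append(
                PatientCourse(
                    patient_id=pid,
                    uln_u_per_ml=uln if uln is not None else DEFAULT_ULN_U_PER_ML,
                    setting=(row["setting"].strip() or "relapse"),
                    lesions=lesions.get(pid, []),
                    ca125=ca125.get(pid, []),
                    treatment_lines=tlines.get(pid, []),
                    death_date=death,
                    therapy_change_dates=changes,
                    last_followup_date=last_fu,
                )
            )
        except ValueError as exc:
            problems.append((ln, f"patients.csv: {exc}"))

    if problems:
        raise RowError(problems)
    return courses


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(
    cohort: Sequence[PatientCourse],
    path: str | Path,
    format: Literal["csv_bundle", "json"] = "csv_bundle",
) -> list[Path]:
    """Write a cohort; ``read_cohort(write_cohort(x))`` round-trips exactly."""
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = {"patients": [c.model_dump(mode="json") for c in cohort]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return [path]
    if format != "csv_bundle":
        raise ValueError(f"unknown format {format!r}")

    path.mkdir(parents=True, exist_ok=True)
    written = []
    with open(path / "patients.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_PATIENT_COLS)
        for c in cohort:
            w.writerow(
                [
                    c.patient_id,
                    _fmt(c.uln_u_per_ml),
                    c.setting,
                    _fmt(c.death_date),
                    _fmt(c.last_followup_date),
                    ";".join(d.isoformat() for d in c.therapy_change_dates),
                ]
            )
    written.append(path / "patients.csv")
    with open(path / "lesions.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_LESION_COLS)
        for c in cohort:
            for m in c.lesions:
                w.writerow(
                    [
                        c.patient_id,
                        m.lesion_id,
                        _fmt(m.timepoint_date),
                        _fmt(m.longest_diameter_mm),
                        _fmt(m.iodine_mg_per_ml),
                        _fmt(m.aortic_iodine_mg_per_ml),
                        m.location,
                    ]
                )
    written.append(path / "lesions.csv")
    with open(path / "ca125.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CA125_COLS)
        for c in cohort:
            for s in c.ca125:
                w.writerow([c.patient_id, _fmt(s.sample_date), _fmt(s.value_u_per_ml)])
    written.append(path / "ca125.csv")
    with open(path / "treatment_lines.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_LINE_COLS)
        for c in cohort:
            for t in c.treatment_lines:
                w.writerow(
                    [c.patient_id, t.line_index, _fmt(t.start_date), _fmt(t.end_date)]
                )
    written.append(path / "treatment_lines.csv")
    return written
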