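"""End-to-end orchestration: simulate -> classify -> survival -> concordance.

Used by the CLI; importable directly for programmatic runs.  All outputs are
plain CSV/JSON and byte-stable for a fixed seed, which the run manifest
(sha256 digests per file) makes checkable.
"""

from __future__ import annotations

import csv
import datetime as dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .ca125 import ca125_progression, classify_gcig
from .cohort import (
    ClassificationResult,
    PatientCourse,
    ResponseCategory,
    write_cohort,
)
from .dect import classify_course_dect, threshold_sweep
from .errors import EvaluabilityError
from .recist import classify_course_recist
from .survival import (
    GroupComparison,
    SurvivalRecord,
    compare_groups,
    concordance,
    derive_pfs,
    km_curve,
    reclassify_nonresponders,
)
from .simulate import SimulationConfig, TruthRecord, simulate_cohort

CriterionName = Literal["recist", "dect", "ca125"]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    simulation: SimulationConfig = SimulationConfig()
    criteria: tuple[CriterionName, ...] = ("recist", "dect", "ca125")
    dect_threshold: float = Field(default=15.0, gt=0)
    dect_aggregate: Literal["sum", "mean"] = "sum"
    dect_normalized: bool = True
    sweep_thresholds: tuple[float, ...] = (10.0, 15.0, 20.0)
    subset: Literal["relapse", "all"] = "relapse"
    death_is_event: bool = True
    reclassify: bool = True


@dataclass
class PatientClassification:
    stream: list[ClassificationResult]
    final: ClassificationResult
    progression_date: Optional[dt.date]


def classify_patient(
    course: PatientCourse,
    criterion: CriterionName,
    dect_threshold: float = 15.0,
    dect_aggregate: str = "sum",
    dect_normalized: bool = True,
    reclassify: bool = True,
) -> PatientClassification:
    """Classify the first treatment line of one patient under one criterion.

    The per-line category is the last non-NE classification; the progression
    date is the first PD (for CA125, the confirmed progression date).  The
    outcome-based non-responder override is applied to the final result unless
    ``reclassify`` is disabled.
    """
    if not course.treatment_lines:
        raise EvaluabilityError(f"patient {course.patient_id} has no treatment line")
    line = course.treatment_lines[0]
    prog_date: Optional[dt.date] = None
    if criterion == "recist":
        stream = classify_course_recist(course, line)
    elif criterion == "dect":
        stream = classify_course_dect(
            course,
            line,
            threshold_percent=dect_threshold,
            mode=dect_aggregate,
            normalized=dect_normalized,
        )
    elif criterion == "ca125":
        stream = [classify_gcig(course, line)]
        progressed, date = ca125_progression(
            course.ca125, line.start_date, course.uln_u_per_ml
        )
        prog_date = date if progressed else None
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    if criterion != "ca125":
        pd_dates = [
            r.assessment_date for r in stream if r.category is ResponseCategory.PD
        ]
        prog_date = min(pd_dates) if pd_dates else None

    non_ne = [r for r in stream if r.category is not ResponseCategory.NE]
    final = non_ne[-1] if non_ne else stream[-1]
    if reclassify:
        final = reclassify_nonresponders([final], course)[0]
    return PatientClassification(stream=stream, final=final, progression_date=prog_date)


def classify_cohort(
    cohort: Sequence[PatientCourse], criterion: CriterionName, **kwargs
) -> dict[str, PatientClassification]:
    return {c.patient_id: classify_patient(c, criterion, **kwargs) for c in cohort}


def survival_records(
    cohort: Sequence[PatientCourse],
    classifications: dict[str, PatientClassification],
    subset: Literal["relapse", "all"] = "relapse",
    death_is_event: bool = True,
) -> list[SurvivalRecord]:
    """Per-patient PFS records for evaluable patients in the chosen subset."""
    records = []
    for course in cohort:
        if subset == "relapse" and course.setting != "relapse":
            continue
        pc = classifications[course.patient_id]
        if pc.final.category is ResponseCategory.NE:
            continue
        records.append(
            derive_pfs(
                course,
                course.treatment_lines[0],
                pc.stream,
                progression_date=pc.progression_date,
                responder=bool(pc.final.responder),
                death_is_event=death_is_event,
            )
        )
    return records


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

_CLS_COLS = [
    "patient_id",
    "criterion",
    "category",
    "percent_change",
    "responder",
    "assessment_date",
    "detail",
]


def write_classifications(results: Sequence[ClassificationResult], path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CLS_COLS)
        for r in results:
            w.writerow(
                [
                    r.patient_id,
                    r.criterion,
                    r.category.value,
                    "" if r.percent_change is None else repr(r.percent_change),
                    "" if r.responder is None else str(r.responder).lower(),
                    r.assessment_date.isoformat(),
                    r.detail,
                ]
            )


def read_classifications(path: Path) -> list[ClassificationResult]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ClassificationResult(
                    patient_id=row["patient_id"],
                    criterion=row["criterion"],
                    category=ResponseCategory(row["category"]),
                    percent_change=(
                        float(row["percent_change"]) if row["percent_change"] else None
                    ),
                    responder=(
                        row["responder"] == "true" if row["responder"] else None
                    ),
                    assessment_date=dt.date.fromisoformat(row["assessment_date"]),
                    detail=row.get("detail", ""),
                )
            )
    return out


def write_survival_outputs(
    records: Sequence[SurvivalRecord],
    comparison: Optional[GroupComparison],
    out_dir: Path,
    criterion: str,
) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    rec_path = out_dir / f"survival_{criterion}_records.csv"
    with open(rec_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "criterion", "time_months", "event", "responder"])
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    r.criterion,
                    repr(r.time_months),
                    str(r.event).lower(),
                    str(r.responder).lower(),
                ]
            )
    paths.append(rec_path)

    km_path = out_dir / f"survival_{criterion}_km.csv"
    with open(km_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["group", "time_months", "survival"])
        for name, flag in (("responder", True), ("nonresponder", False)):
            grp = [r for r in records if r.responder == flag]
            if not grp:
                continue
            curve = km_curve(grp)
            for t, s in zip(curve.times, curve.survival):
                w.writerow([name, repr(t), repr(s)])
    paths.append(km_path)

    if comparison is not None:
        summary_path = out_dir / f"survival_{criterion}_summary.json"
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "criterion": comparison.criterion,
                    "n_responders": comparison.n_responders,
                    "n_nonresponders": comparison.n_nonresponders,
                    "median_responder": comparison.median_responder,
                    "median_nonresponder": comparison.median_nonresponder,
                    "chi2": comparison.chi2,
                    "p": comparison.p_value,
                    "hr": comparison.hr,
                    "ci": [comparison.ci_low, comparison.ci_high],
                },
                fh,
                indent=1,
            )
            fh.write("\n")
        paths.append(summary_path)
    return paths


def write_truth(truth: Sequence[TruthRecord], path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "patient_id",
                "responder",
                "setting",
                "true_pfs_months",
                "observed_months",
                "event",
            ]
        )
        for t in truth:
            w.writerow(
                [
                    t.patient_id,
                    str(t.responder).lower(),
                    t.setting,
                    repr(t.true_pfs_months),
                    repr(t.observed_months),
                    str(t.event).lower(),
                ]
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    row_counts: dict[str, int]
    digests: dict[str, str]

    def to_json(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "row_counts": self.row_counts,
            "digests": self.digests,
        }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Simulate, classify under every configured criterion, derive survival,
    cross-tabulate concordance, sweep thresholds, and write a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    row_counts: dict[str, int] = {}
    outputs: list[Path] = []

    cohort, truth = simulate_cohort(config.simulation)
    outputs.extend(write_cohort(cohort, out_dir / "cohort"))
    truth_path = out_dir / "truth.csv"
    write_truth(truth, truth_path)
    outputs.append(truth_path)
    row_counts["simulate.patients"] = len(cohort)
    row_counts["simulate.lesions"] = sum(len(c.lesions) for c in cohort)

    latent = {t.patient_id: t.responder for t in truth}
    per_criterion: dict[str, dict[str, PatientClassification]] = {}
    for criterion in config.criteria:
        cls = classify_cohort(
            cohort,
            criterion,
            dect_threshold=config.dect_threshold,
            dect_aggregate=config.dect_aggregate,
            dect_normalized=config.dect_normalized,
            reclassify=config.reclassify,
        )
        per_criterion[criterion] = cls
        path = out_dir / f"classifications_{criterion}.csv"
        write_classifications(
            [cls[c.patient_id].final for c in cohort], path
        )
        outputs.append(path)
        row_counts[f"classify.{criterion}"] = len(cls)

    # waterfall-style table: percent change aligned with response duration
    waterfall_path = out_dir / "waterfall.csv"
    with open(waterfall_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["patient_id", "criterion", "percent_change", "responder", "pfs_months", "event"]
        )
        for criterion in config.criteria:
            cls = per_criterion[criterion]
            recs = {
                r.patient_id: r
                for r in survival_records(
                    cohort, cls, subset=config.subset, death_is_event=config.death_is_event
                )
            }
            for course in cohort:
                pc = cls[course.patient_id]
                rec = recs.get(course.patient_id)
                if rec is None:
                    continue
                w.writerow(
                    [
                        course.patient_id,
                        criterion,
                        ""
                        if pc.final.percent_change is None
                        else repr(pc.final.percent_change),
                        str(rec.responder).lower(),
                        repr(rec.time_months),
                        str(rec.event).lower(),
                    ]
                )
    outputs.append(waterfall_path)

    for criterion in config.criteria:
        recs = survival_records(
            cohort,
            per_criterion[criterion],
            subset=config.subset,
            death_is_event=config.death_is_event,
        )
        row_counts[f"survival.{criterion}"] = len(recs)
        comparison = None
        if any(r.responder for r in recs) and any(not r.responder for r in recs):
            comparison = compare_groups(recs)
        outputs.extend(write_survival_outputs(recs, comparison, out_dir, criterion))

    pairs = [
        ("dect", "recist"),
        ("dect", "ca125"),
    ]
    for a, b in pairs:
        if a not in config.criteria or b not in config.criteria:
            continue
        table = concordance(
            [per_criterion[a][c.patient_id].final for c in cohort],
            [per_criterion[b][c.patient_id].final for c in cohort],
        )
        path = out_dir / f"concordance_{a}_{b}.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                [f"{a}_category", f"{b}_category", "count", "row_agreement_percent"]
            )
            for (rcat, ccat), count in sorted(table.counts.items()):
                w.writerow([rcat, ccat, count, table.agreement_percent(rcat, ccat)])
        outputs.append(path)
        row_counts[f"concordance.{a}_{b}"] = table.n

    if "dect" in config.criteria:
        deltas, labels = [], []
        for course in cohort:
            pc = per_criterion["dect"][course.patient_id]
            if (
                pc.final.category is ResponseCategory.NE
                or pc.final.percent_change is None
            ):
                continue
            deltas.append(pc.final.percent_change)
            labels.append(latent[course.patient_id])
        sweep = threshold_sweep(deltas, labels, config.sweep_thresholds)
        sweep_path = out_dir / "sweep.json"
        with open(sweep_path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "selected_threshold": sweep.selected_threshold,
                    "metrics": [
                        {
                            "threshold": m.threshold,
                            "accuracy": m.accuracy,
                            "sensitivity_pd": m.sensitivity_pd,
                            "specificity_pd": m.specificity_pd,
                            "balanced_accuracy": m.balanced_accuracy,
                            "pd_calls": m.pd_calls,
                            "pr_calls": m.pr_calls,
                        }
                        for m in sweep.metrics
                    ],
                },
                fh,
                indent=1,
            )
            fh.write("\n")
        outputs.append(sweep_path)
        row_counts["sweep.patients"] = len(deltas)

    manifest = RunManifest(
        config=json.loads(config.model_dump_json()),
        seed=config.simulation.seed,
        version=__version__,
        row_counts=row_counts,
        digests={
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(outputs)
        },
    )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
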