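"""Synthetic relapsed-ovarian-cancer cohort generator.

A latent responder status drives correlated lesion shrinkage, iodine-
concentration decline, CA125 decline and longer exponential time to
progression; non-responders get the reverse drifts.  Imaging sits at baseline
/ ~3 months / ~6 months of a single treatment line, CA125 is sampled roughly
monthly, and all positive quantities carry multiplicative log-normal
measurement noise.  Generation is fully deterministic given the seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._util import MONTH_DAYS
from .cohort import (
    CA125Sample,
    LesionMeasurement,
    PatientCourse,
    ResponseCategory,
    TreatmentLine,
)

ANCHOR_DATE = dt.date(2020, 1, 1)
SCAN_DAYS = (0, 91, 182)
CA125_SAMPLE_DAYS = (0, 30, 61, 91, 122, 152, 182)


class LogNormalParams(BaseModel):
    model_config = ConfigDict(frozen=True)
    mu: float
    sigma: float = Field(ge=0)


class TruncNormalParams(BaseModel):
    model_config = ConfigDict(frozen=True)
    mean: float = Field(gt=0)
    sd: float = Field(ge=0)
    minimum: float = Field(gt=0, default=1.0)


class GroupValues(BaseModel):
    """Per-latent-group scalar (responder vs non-responder)."""

    model_config = ConfigDict(frozen=True)
    responder: float
    non_responder: float

    def for_group(self, responder: bool) -> float:
        return self.responder if responder else self.non_responder


class Ca125Kinetics(BaseModel):
    model_config = ConfigDict(frozen=True)
    pretreatment: LogNormalParams = LogNormalParams(mu=math.log(250.0), sigma=0.6)
    #: log-scale decline per month for responders (positive = falling)
    decline_rate_per_month: float = Field(default=0.5, ge=0)
    #: log-scale rise per month for non-responders (positive = rising)
    rise_rate_per_month: float = Field(default=0.35, ge=0)


class NoiseCv(BaseModel):
    model_config = ConfigDict(frozen=True)
    size: float = Field(default=0.05, ge=0)
    iodine: float = Field(default=0.08, ge=0)
    ca125: float = Field(default=0.10, ge=0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=40, gt=0)
    responder_fraction: float = Field(default=0.69, ge=0, le=1)
    relapse_fraction: float = Field(default=0.8, ge=0, le=1)
    n_lesions_range: tuple[int, int] = (1, 5)
    baseline_diameter_mm: LogNormalParams = LogNormalParams(
        mu=math.log(25.0), sigma=0.4
    )
    baseline_iodine_mg_per_ml: LogNormalParams = LogNormalParams(
        mu=math.log(1.5), sigma=0.35
    )
    #: drawn per scan (contrast timing varies), so normalization matters;
    #: set sd = 0 for a noiseless acquisition
    aortic_iodine_mg_per_ml: TruncNormalParams = TruncNormalParams(
        mean=7.0, sd=0.7, minimum=1.0
    )
    #: total percent change in SLD realised at the day-182 end-of-line scan
    size_effect: GroupValues = GroupValues(responder=-35.0, non_responder=25.0)
    #: total percent change in aggregate iodine at the day-182 scan
    iodine_effect: GroupValues = GroupValues(responder=-30.0, non_responder=30.0)
    ca125_kinetics: Ca125Kinetics = Ca125Kinetics()
    #: exponential PFS scale (months) per latent group
    hazard_months: GroupValues = GroupValues(responder=10.0, non_responder=5.0)
    censoring_months: float = Field(default=18.0, gt=0)
    measurement_cv: NoiseCv = NoiseCv()
    uln_u_per_ml: float = Field(default=35.0, gt=0)
    #: exactly this many patients keep iodine values only at the baseline scan
    n_single_scan: int = Field(default=0, ge=0)
    #: probability that a progression event triggers a recorded therapy change
    therapy_change_prob: float = Field(default=0.7, ge=0, le=1)
    #: probability that a progressing patient dies during follow-up
    death_prob: float = Field(default=0.2, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.n_lesions_range
        if lo < 1 or hi < lo:
            raise ValueError("n_lesions_range must satisfy 1 <= lo <= hi")
        if self.n_single_scan > self.n_patients:
            raise ValueError("n_single_scan exceeds n_patients")
        return self


@dataclass(frozen=True)
class TruthRecord:
    """Latent ground truth for one simulated patient."""

    patient_id: str
    responder: bool
    setting: str
    true_pfs_months: float
    observed_months: float
    event: bool


def _lognormal_noise(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


def _drift_factor(total_effect_percent: float, day: int, horizon: int = 182) -> float:
    """Multiplicative trajectory reaching 1 + effect/100 exactly at the horizon."""
    return (1.0 + total_effect_percent / 100.0) ** (day / horizon)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientCourse], list[TruthRecord]]:
    """Generate a validated cohort plus latent ground-truth labels."""
    rng = np.random.default_rng(config.seed)
    single_scan_ids: set[int] = set()
    if config.n_single_scan:
        single_scan_ids = set(
            rng.choice(config.n_patients, size=config.n_single_scan, replace=False)
        )

    courses: list[PatientCourse] = []
    truth: list[TruthRecord] = []
    cv = config.measurement_cv
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        responder = bool(rng.random() < config.responder_fraction)
        setting = "relapse" if rng.random() < config.relapse_fraction else "first_line"
        start = ANCHOR_DATE

        t_true = float(rng.exponential(config.hazard_months.for_group(responder)))
        event = t_true <= config.censoring_months
        observed = min(t_true, config.censoring_months)
        progression_day = int(round(observed * MONTH_DAYS))

        lo, hi = config.n_lesions_range
        n_lesions = int(rng.integers(lo, hi + 1))
        size_eff = config.size_effect.for_group(responder)
        iod_eff = config.iodine_effect.for_group(responder)
        base_diam = np.exp(
            rng.normal(
                config.baseline_diameter_mm.mu,
                config.baseline_diameter_mm.sigma,
                n_lesions,
            )
        )
        base_iod = np.exp(
            rng.normal(
                config.baseline_iodine_mg_per_ml.mu,
                config.baseline_iodine_mg_per_ml.sigma,
                n_lesions,
            )
        )

        lesions: list[LesionMeasurement] = []
        for s_idx, day in enumerate(SCAN_DAYS):
            scan_date = start + dt.timedelta(days=day)
            aorta = max(
                float(
                    rng.normal(
                        config.aortic_iodine_mg_per_ml.mean,
                        config.aortic_iodine_mg_per_ml.sd,
                    )
                ),
                config.aortic_iodine_mg_per_ml.minimum,
            )
            iodine_here = s_idx == 0 or i not in single_scan_ids
            for j in range(n_lesions):
                diam = (
                    base_diam[j]
                    * _drift_factor(size_eff, day)
                    * _lognormal_noise(rng, cv.size)
                )
                iod = (
                    base_iod[j]
                    * _drift_factor(iod_eff, day)
                    * _lognormal_noise(rng, cv.iodine)
                )
                lesions.append(
                    LesionMeasurement(
                        lesion_id=f"L{j + 1}",
                        timepoint_date=scan_date,
                        longest_diameter_mm=float(diam),
                        iodine_mg_per_ml=float(iod) if iodine_here else None,
                        aortic_iodine_mg_per_ml=aorta if iodine_here else None,
                        location="peritoneum",
                    )
                )

        pre_ca125 = float(
            np.exp(
                rng.normal(
                    config.ca125_kinetics.pretreatment.mu,
                    config.ca125_kinetics.pretreatment.sigma,
                )
            )
        )
        rate = (
            -config.ca125_kinetics.decline_rate_per_month
            if responder
            else config.ca125_kinetics.rise_rate_per_month
        )
        samples = []
        for day in CA125_SAMPLE_DAYS:
            months = day / MONTH_DAYS
            value = pre_ca125 * math.exp(rate * months) * _lognormal_noise(rng, cv.ca125)
            samples.append(
                CA125Sample(
                    sample_date=start + dt.timedelta(days=day),
                    value_u_per_ml=max(value, 1e-6),
                )
            )

        therapy_changes: list[dt.date] = []
        death_date: Optional[dt.date] = None
        if event and rng.random() < config.therapy_change_prob:
            therapy_changes.append(start + dt.timedelta(days=progression_day + 14))
        if event and rng.random() < config.death_prob:
            death_day = max(progression_day + 60, SCAN_DAYS[-1] + 31)
            death_date = start + dt.timedelta(days=death_day)
        fu_candidates = [SCAN_DAYS[-1] + 1, progression_day]
        if therapy_changes:
            fu_candidates.append((therapy_changes[-1] - start).days)
        last_fu = start + dt.timedelta(days=max(fu_candidates))
        if death_date is not None:
            last_fu = death_date

        courses.append(
            PatientCourse(
                patient_id=pid,
                uln_u_per_ml=config.uln_u_per_ml,
                setting=setting,
                lesions=lesions,
                ca125=samples,
                treatment_lines=[
                    TreatmentLine(
                        line_index=1,
                        start_date=start,
                        end_date=start + dt.timedelta(days=SCAN_DAYS[-1]),
                    )
                ],
                death_date=death_date,
                therapy_change_dates=therapy_changes,
                last_followup_date=last_fu,
            )
        )
        truth.append(
            TruthRecord(
                patient_id=pid,
                responder=responder,
                setting=setting,
                true_pfs_months=t_true,
                observed_months=observed,
                event=event,
            )
        )
    return courses, truth


def survival_records_from_truth(truth, criterion: str = "DECT"):
    """Latent-truth PFS records (used for parameter-recovery checks)."""
    from .survival import SurvivalRecord

    return [
        SurvivalRecord(
            patient_id=t.patient_id,
            criterion=criterion,
            time_months=t.observed_months,
            event=t.event,
            responder=t.responder,
        )
        for t in truth
    ]


@dataclass(frozen=True)
class RecoveryReport:
    """Per-criterion recovery of the latent responder status."""

    accuracy: dict[str, float]
    n_evaluable: dict[str, int]
    confusion: dict[str, dict[tuple[bool, bool], int]]


def classification_recovery(
    config: SimulationConfig, threshold_percent: float = 15.0
) -> RecoveryReport:
    """Run all three engines on a simulated cohort and tabulate how well each
    recovers the latent responder label (evaluable patients only)."""
    from .ca125 import classify_gcig
    from .dect import classify_course_dect
    from .recist import classify_course_recist

    cohort, truth = simulate_cohort(config)
    latent = {t.patient_id: t.responder for t in truth}
    accuracy: dict[str, float] = {}
    n_eval: dict[str, int] = {}
    confusion: dict[str, dict[tuple[bool, bool], int]] = {}
    for criterion in ("RECIST", "DECT", "CA125"):
        conf: dict[tuple[bool, bool], int] = {}
        hits = total = 0
        for course in cohort:
            line = course.treatment_lines[0]
            if criterion == "RECIST":
                results = classify_course_recist(course, line)
                final = results[-1]
            elif criterion == "DECT":
                results = classify_course_dect(
                    course, line, threshold_percent=threshold_percent
                )
                final = results[-1]
            else:
                final = classify_gcig(course, line)
            if final.category is ResponseCategory.NE:
                continue
            pred = bool(final.responder)
            key = (latent[course.patient_id], pred)
            conf[key] = conf.get(key, 0) + 1
            hits += key[0] == key[1]
            total += 1
        accuracy[criterion] = hits / total if total else float("nan")
        n_eval[criterion] = total
        confusion[criterion] = conf
    return RecoveryReport(accuracy=accuracy, n_evaluable=n_eval, confusion=confusion)
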