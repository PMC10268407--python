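import datetime as dt

import pytest

from dectresp.cohort import (
    CA125Sample,
    LesionMeasurement,
    PatientCourse,
    TreatmentLine,
)

START = dt.date(2020, 1, 1)


def day(n: int) -> dt.date:
    return START + dt.timedelta(days=n)


def make_course(
    patient_id="P1",
    lesion_specs=None,
    ca125_specs=None,
    uln=35.0,
    setting="relapse",
    death_day=None,
    therapy_change_days=(),
    last_followup_day=400,
    line_days=((0, 182),),
):
    """Compact patient-course builder.

    ``lesion_specs``: {lesion_id: {day: (diameter, iodine, aorta)}} with
    iodine/aorta optional.  ``ca125_specs``: {day: value}.
    """
    lesions = []
    for lid, by_day in (lesion_specs or {}).items():
        for d, vals in by_day.items():
            diam, iod, aorta = (tuple(vals) + (None, None))[:3]
            lesions.append(
                LesionMeasurement(
                    lesion_id=lid,
                    timepoint_date=day(d),
                    longest_diameter_mm=diam,
                    iodine_mg_per_ml=iod,
                    aortic_iodine_mg_per_ml=aorta,
                )
            )
    ca125 = [
        CA125Sample(sample_date=day(d), value_u_per_ml=v)
        for d, v in (ca125_specs or {}).items()
    ]
    lines = [
        TreatmentLine(line_index=i + 1, start_date=day(s), end_date=day(e) if e else None)
        for i, (s, e) in enumerate(line_days)
    ]
    return PatientCourse(
        patient_id=patient_id,
        uln_u_per_ml=uln,
        setting=setting,
        lesions=lesions,
        ca125=ca125,
        treatment_lines=lines,
        death_date=day(death_day) if death_day is not None else None,
        therapy_change_dates=[day(d) for d in therapy_change_days],
        last_followup_date=day(last_followup_day),
    )


@pytest.fixture
def simple_course():
    """One lesion, measured at baseline and two follow-ups with iodine."""
    return make_course(
        lesion_specs={
            "L1": {
                0: (29.8, 1.4, 7.0),
                91: (35.0, 1.1, 7.0),
                182: (32.0, 1.0, 7.0),
            }
        },
        ca125_specs={0: 200.0, 30: 120.0, 61: 95.0, 91: 92.0, 122: 60.0},
    )
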