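# dectresp

Comparative tumour-response assessment for ovarian-cancer cohorts: three
response-criteria engines — size-based (sum of longest diameters), serum
CA125 (GCIG-style rules), and a dual-energy-CT iodine-concentration
criterion — plus per-criterion progression-free-survival derivation
(Kaplan-Meier, log-rank, hazard ratio), cross-criterion concordance tables,
and a synthetic longitudinal cohort generator so the whole pipeline is
testable without patient data.

## Layout

| module                | what it does |
|-----------------------|--------------|
| `dectresp.cohort`     | domain types (`PatientCourse`, `LesionMeasurement`, …), CSV-bundle/JSON readers and writers, the ≥2-iodine-timepoint eligibility filter |
| `dectresp.recist`     | SLD computation and CR/PR/SD/PD classification (baseline-referenced by default, strict nadir+5 mm mode behind a flag) |
| `dectresp.ca125`      | eligibility gate (≥ 2×ULN), confirmed 50%-fall response, confirmed 2×nadir/ULN progression, composed classification |
| `dectresp.dect`       | aortic normalization, iodine aggregation, ±15% classification with the any-decrease responder flag, 10/15/20% threshold sweep |
| `dectresp.survival`   | PFS derivation, outcome-based non-responder override, KM/log-rank/Mantel-Haenszel HR, concordance tables |
| `dectresp.simulate`   | seeded synthetic cohorts with latent responder status driving all modalities, plus ground-truth labels |
| `dectresp.pipeline` / `dectresp.cli` | end-to-end orchestration with a reproducibility manifest |

## CLI

```sh
dectresp --seed 1 simulate --out runs/sim          # cohort bundle + truth.csv
dectresp classify --criterion dect --in runs/sim/cohort --out dect.csv \
    --threshold 15 --aggregate sum --normalized
dectresp survival --criterion dect --in runs/sim/cohort --subset relapse --out runs/surv
dectresp concordance --a dect --b ca125 --in runs/sim/cohort --out conc.csv
dectresp sweep --in runs/sim/cohort --truth runs/sim/truth.csv --thresholds 10,15,20
dectresp --seed 1 run --out runs/full              # whole pipeline + manifest.json
```

Exit codes: 0 success, 2 validation error, 3 stage failure. Logs go to
stderr; add the global `--json` flag for machine-readable stdout.

Cohort interchange: a CSV bundle (`patients.csv`, `lesions.csv`, `ca125.csv`,
`treatment_lines.csv`, ISO-8601 dates, diameters in mm) or a single JSON
document; `read_cohort(write_cohort(x)) == x`.

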