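# glycovar

Analysis pipeline relating visit-to-visit HbA1c variability to kidney-function
decline in longitudinal EMR-style diabetes cohorts:

- **synthdata** — synthetic generator for the five raw tables (subjects,
  visits, labs, meds, diagnoses). Each subject carries a latent variability
  band that controls the probability of successive HbA1c changes ≥ 0.5%, a
  planted true eGFR slope (creatinine obtained by inverting CKD-EPI at the
  attained age), and band-dependent covariate prevalences so the downstream
  balancing faces genuine confounding.
- **cohort** — eligibility rules (≥5 visits over ≥1 year from the first
  HbA1c, ≥3 creatinine measures, baseline eGFR ≥ 15, adults), index/end
  dates, baseline capture in a (−30, +365)-day window (nearest measurement,
  ties to the earlier one), adherence (visits/year), comorbidity flags from
  configurable ICD-10 prefixes. Every excluded subject is logged under
  exactly one reason, evaluated in a fixed priority order.
- **measures** — CKD-EPI (2009 creatinine) eGFR, HbA1c variability score
  (percent of successive changes ≥ 0.5%, inclusive), its five 20%-wide
  categories, time-weighted average HbA1c, NGSP→IFCC conversion,
  per-subject OLS eGFR slopes (full or windowed), rapid-decline rule
  (slope ≤ −5 mL/min/1.73 m²/yr).
- **balancing** — entropy balancing: exponential-tilting weights with exact
  first-moment balance of nine covariates across the five categories,
  solved per category by damped Newton on the convex dual; SMD diagnostics
  before/after.
- **models** — weighted logistic regression of the rapid-decline flag on
  category indicators (probability-weight sandwich CIs) and a weighted
  linear mixed model of eGFR on category × time with random intercept and
  slope per subject (subject-level likelihood weights, ML, Wald CIs,
  0.75 mL/min/1.73 m²/yr minimal-important-difference flag). Subgroup
  (sex, age, insulin, baseline eGFR) and sensitivity (2/3/4/5-year
  windowed slopes, ≥90-day unparallel-last-measures exclusion,
  baseline-HbA1c weighting, baseline eGFR < 30 exclusion, SGLT2i/GLP-1RA
  exclusion) suites.
- **report** — Table-1-style descriptive summary (median [Q1, Q3] /
  n (%)), end-to-end orchestration with a run manifest.

## CLI

```bash
glycovar simulate --config cfg.yaml --seed 1 --out tables/
glycovar build-cohort --tables tables/ --out cohortdir/
glycovar balance --cohort cohortdir/cohort.csv --out cohortdir/
glycovar fit --cohort cohortdir/cohort.csv --long-egfr cohortdir/long_egfr.csv \
             --weights cohortdir/weights.csv --out estimates.json
glycovar report --cohort cohortdir/cohort.csv --out table1.csv
# or end-to-end:
glycovar run --config cfg.yaml --seed 1 --out results/
```

`cfg.yaml` holds `SimConfig` fields (see `glycovar/config.py`); all outputs
are CSV/JSON with ISO-8601 dates. Runs are deterministic given the seed.

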