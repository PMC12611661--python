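# neuroclaims

Case-finding and burden estimation for parkinsonism and dementia from four
linked administrative health databases: a population registry, outpatient
drug prescriptions (ATC-coded), hospital discharge records (up to six ICD-9
diagnoses), and chronic-disease co-payment exemptions.

The package covers the full pipeline:

* **records** — typed schemas for the four sources, CSV/Parquet readers with
  row-level rejection reporting, keyed pseudonymization (HMAC-SHA256), and
  assembly of per-person event histories with orphan-event accounting.
* **simulate** — a synthetic region generator with planted age/sex-graded
  disease prevalence and incidence, tracer-prescription repetition,
  psychiatric confounders, deaths, and municipality assignment. The planted
  truth table makes every downstream stage testable offline.
* **codebook** — configurable ATC / ICD-9 / exemption code sets (YAML),
  with documented defaults: antiparkinsonians + exemption 038 for
  parkinsonism; anti-dementia drugs, dementia ICD-9 diagnoses, a dementia
  exemption, and a proxy criterion (antipsychotics N05A, trazodone,
  mirtazapine) for dementia, the proxy vetoed by psychiatric labels.
* **identify** — adjudication of each person into parkinsonism / dementia /
  both, with per-source and per-drug attribution, and incident-case
  flagging via a disease-free look-back (default 5 years, truncated at the
  study window start).
* **rates** — crude, age-specific and directly standardized rates (bundled
  WHO 2000–2025 and Eurostat ESP standard populations, renormalized over
  the analyzed age range), Wilson score CIs, percentile-bootstrap CIs for
  adjusted rates (person resampling), and Poisson log-normal intervals for
  incidence rate ratios. Rates are per 1,000, rounded half-up to 2 decimals
  in outputs.
* **geo** — municipality-level counts and rates with GeoJSON/CSV export.
  Municipal rates are raw (unsmoothed); small denominators are noisy.

## CLI

```sh
# generate a synthetic fixture (four CSVs + truth.csv + config)
neuroclaims simulate --config run.yaml --seed 1 --out fixture/

# adjudicate cases
neuroclaims identify --data-dir fixture/ --out results/ --study-start-year 2016

# burden tables and year-on-year IRRs
neuroclaims rates --data-dir fixture/ --config run.yaml --out results/

# municipal aggregation (GeoJSON with --geometry, else CSV)
neuroclaims geo --data-dir fixture/ --out results/

# everything end to end, with a stage-count run log
neuroclaims run-all --config run.yaml --seed 1 --out results/
```

A minimal `run.yaml`:

```yaml
simulate:
  n_persons: 50000
  seed: 1
  n_municipalities: 12
reference_year: 2021
study_start_year: 2016
lookback_years: 5
standards: [who, eurostat]
```

Replace the `simulate:` block with `sources: path/to/dir` to run on real
extracts (`registry.csv`, `prescriptions.csv`, `discharges.csv`,
`exemptions.csv` with the documented headers).

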