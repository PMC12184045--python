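# amyelig

Eligibility analytics for amyloid-targeting immunotherapies (aducanumab,
lecanemab, donanemab) from joint clinical baseline and post-mortem
neuropathology records.

The pipeline classifies participants with an amnestic AD syndrome at
baseline (global CDR 0.5/1, at least mild CDR memory-box impairment,
clinician-assigned AD etiology), anchors amyloid positivity in autopsy
Thal phase (3–5 ≙ PET-positive; >0 as the wider sensitivity definition),
derives the four-level NIA-AA ABC summary from Thal/Braak/CERAD, applies
declarative trial/AUR criteria sets through a staged funnel (clinical
inclusion → amyloid → optional intermediate-tau → exclusions) with a
per-rule audit trail, and reports funnel percentages, CDR composition,
full-AD-pathology shares, co-pathology prevalence, and exact Euler region
overlaps. A synthetic cohort generator with a latent-severity model
stands in for access-controlled registry data.

## Library overview

| Module | Contents |
| --- | --- |
| `amyelig.cohort_io` | `ParticipantRecord`/`NeuropathRecord`/`Cohort`, codebook-driven CSV/TSV read/write, validation |
| `amyelig.staging` | A/B/C binnings, 64-cell ABC summary matrix (editable data file), `amyloid_positive`, `tau_intermediate` |
| `amyelig.syndrome` | `classify_syndrome`, `base_population` |
| `amyelig.engine` | `CriterionRule`/`CriteriaProfile`, `apply_profile` with `EligibilityTrace`s, `funnel_counts`, five bundled profiles |
| `amyelig.analytics` | `percent_int` (nearest integer, halves away from zero), funnel reports, `euler_regions`, co-pathology/CDR/ABC composition tables |
| `amyelig.synthetic` | `SyntheticCohortConfig`, `generate_cohort`, `calibration_report` |

Bundled criteria profiles (`emerge_engage_aducanumab`,
`clarity_ad_lecanemab`, `trailblazer_alz2_donanemab`, `aur_aducanumab`,
`aur_lecanemab`) are best-effort public operationalizations and are
meant to be edited; engine correctness is tested independently of their
content. MRI-dependent exclusions are representable but not bundled.

## CLI

```sh
amyelig generate --out data/ --n 2000 --seed 1
amyelig validate data/clinical.csv data/neuropath.csv
amyelig classify-syndrome data/clinical.csv data/neuropath.csv
amyelig funnel   data/clinical.csv data/neuropath.csv --profile clarity_ad_lecanemab
amyelig select   data/clinical.csv data/neuropath.csv --profile trailblazer_alz2_donanemab --tau
amyelig overlap  data/clinical.csv data/neuropath.csv --profiles emerge_engage_aducanumab,clarity_ad_lecanemab
amyelig copathology data/clinical.csv data/neuropath.csv --profile aur_lecanemab
amyelig report   data/clinical.csv data/neuropath.csv --out report/
```

Source tables in other dialects are translated by a codebook
(`--codebook`); see `src/amyelig/data/codebooks/nacc_example.yaml`.

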