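# Best-effort operationalization of the EMERGE/ENGAGE (aducanumab) phase 3
# selection criteria on the harmonized schema.  Criteria that depend on data
# unavailable at baseline (MRI findings, APOE, biomarkers) are not encoded.
# Rule content is editable data; provenance labels cite the public protocol.
profile_id: emerge_engage_aducanumab
description: "Aducanumab phase 3 trials (EMERGE/ENGAGE): MCI-only window."
amyloid_mode: pet_equivalent
tau_rule_enabled: false
inclusion:
  - rule_id: age_window
    field: age_years
    range: {lo: 50, hi: 85}
    provenance: "EMERGE/ENGAGE protocol: age 50-85"
  - rule_id: cdr_stage
    field: cdr_global
    equals: 0.5
    provenance: "EMERGE/ENGAGE protocol: global CDR 0.5 only"
  - rule_id: mmse_window
    field: mmse
    range: {lo: 24, hi: 30}
    provenance: "EMERGE/ENGAGE protocol: MMSE 24-30"
exclusion:
  - rule_id: no_stroke_or_tia
    field: comorbidity.stroke_or_tia
    flag_false: true
    provenance: "EMERGE/ENGAGE protocol: stroke/TIA history"
  - rule_id: no_seizures
    field: comorbidity.seizures
    flag_false: true
    provenance: "EMERGE/ENGAGE protocol: seizure disorder"
  - rule_id: no_unstable_psychiatric
    field: comorbidity.unstable_psychiatric
    flag_false: true
    provenance: "EMERGE/ENGAGE protocol: unstable psychiatric illness"
  - rule_id: no_bleeding_disorder
    field: comorbidity.bleeding_disorder
    flag_false: true
    provenance: "EMERGE/ENGAGE protocol: bleeding disorder"
  - rule_id: no_active_cancer
    field: comorbidity.cancer_active
    flag_false: true
    provenance: "EMERGE/ENGAGE protocol: active malignancy"
  - rule_id: no_anticoagulants
    field: medication.anticoagulant_use
    flag_false: true
    provenance: "EMERGE/ENGAGE protocol: anticoagulant medication"
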