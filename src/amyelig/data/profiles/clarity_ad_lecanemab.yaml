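# Best-effort operationalization of the CLARITY-AD (lecanemab) phase 3
# selection criteria on the harmonized schema.  MRI-, APOE- and
# biomarker-dependent criteria are not encoded (data unavailable).
profile_id: clarity_ad_lecanemab
description: "Lecanemab phase 3 trial (CLARITY-AD): MCI and mild dementia."
amyloid_mode: pet_equivalent
tau_rule_enabled: false
inclusion:
  - rule_id: age_window
    field: age_years
    range: {lo: 50, hi: 90}
    provenance: "CLARITY-AD protocol: age 50-90"
  - rule_id: cdr_stage
    field: cdr_global
    in_set: [0.5, 1]
    provenance: "CLARITY-AD protocol: global CDR 0.5 or 1"
  - rule_id: mmse_window
    field: mmse
    range: {lo: 22, hi: 30}
    provenance: "CLARITY-AD protocol: MMSE 22-30"
exclusion:
  - rule_id: no_stroke_or_tia
    field: comorbidity.stroke_or_tia
    flag_false: true
    provenance: "CLARITY-AD protocol: cerebrovascular event history"
  - rule_id: no_seizures
    field: comorbidity.seizures
    flag_false: true
    provenance: "CLARITY-AD protocol: seizure disorder"
  - rule_id: no_unstable_psychiatric
    field: comorbidity.unstable_psychiatric
    flag_false: true
    provenance: "CLARITY-AD protocol: unstable psychiatric illness"
  - rule_id: no_bleeding_disorder
    field: comorbidity.bleeding_disorder
    flag_false: true
    provenance: "CLARITY-AD protocol: bleeding disorder"
  - rule_id: no_anticoagulants
    field: medication.anticoagulant_use
    flag_false: true
    provenance: "CLARITY-AD protocol: anticoagulant medication"
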