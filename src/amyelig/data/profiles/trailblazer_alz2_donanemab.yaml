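# Best-effort operationalization of the TRAILBLAZER-ALZ 2 (donanemab)
# phase 3 selection criteria on the harmonized schema.  The intermediate
# tau-spread stage (Braak 3-4 standing in for the tau-PET criterion) is
# switchable and disabled by default: tau spreads between baseline and
# autopsy, so the autopsy stage overstates baseline tau.
profile_id: trailblazer_alz2_donanemab
description: "Donanemab phase 3 trial (TRAILBLAZER-ALZ 2): MCI and mild dementia."
amyloid_mode: pet_equivalent
tau_rule_enabled: false
inclusion:
  - rule_id: age_window
    field: age_years
    range: {lo: 60, hi: 85}
    provenance: "TRAILBLAZER-ALZ 2 protocol: age 60-85"
  - rule_id: cdr_stage
    field: cdr_global
    in_set: [0.5, 1]
    provenance: "TRAILBLAZER-ALZ 2 protocol: global CDR 0.5 or 1"
  - rule_id: mmse_window
    field: mmse
    range: {lo: 20, hi: 28}
    provenance: "TRAILBLAZER-ALZ 2 protocol: MMSE 20-28"
exclusion:
  - rule_id: no_stroke_or_tia
    field: comorbidity.stroke_or_tia
    flag_false: true
    provenance: "TRAILBLAZER-ALZ 2 protocol: cerebrovascular event history"
  - rule_id: no_seizures
    field: comorbidity.seizures
    flag_false: true
    provenance: "TRAILBLAZER-ALZ 2 protocol: seizure disorder"
  - rule_id: no_unstable_psychiatric
    field: comorbidity.unstable_psychiatric
    flag_false: true
    provenance: "TRAILBLAZER-ALZ 2 protocol: unstable psychiatric illness"
  - rule_id: no_active_cancer
    field: comorbidity.cancer_active
    flag_false: true
    provenance: "TRAILBLAZER-ALZ 2 protocol: active malignancy"
  - rule_id: no_anticoagulants
    field: medication.anticoagulant_use
    flag_false: true
    provenance: "TRAILBLAZER-ALZ 2 protocol: anticoagulant medication"
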