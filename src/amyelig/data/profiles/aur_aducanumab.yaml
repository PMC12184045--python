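# Best-effort operationalization of the aducanumab appropriate use
# recommendations (AUR).  The AUR widen the trial window to MCI or mild
# dementia (the trials required global CDR 0.5 only) and lower the MMSE
# floor; safety-based exclusions largely follow the trials.
profile_id: aur_aducanumab
description: "Aducanumab appropriate use recommendations: MCI or mild dementia."
amyloid_mode: pet_equivalent
tau_rule_enabled: false
inclusion:
  - rule_id: age_window
    field: age_years
    range: {lo: 50, hi: 90}
    provenance: "Aducanumab AUR: early symptomatic AD age range"
  - rule_id: cdr_stage
    field: cdr_global
    in_set: [0.5, 1]
    provenance: "Aducanumab AUR: MCI or mild dementia (no CDR-0.5 restriction)"
  - rule_id: mmse_floor
    field: mmse
    range: {lo: 21, hi: 30}
    provenance: "Aducanumab AUR: MMSE 21-30"
exclusion:
  - rule_id: no_stroke_or_tia
    field: comorbidity.stroke_or_tia
    flag_false: true
    provenance: "Aducanumab AUR: cerebrovascular event history"
  - rule_id: no_seizures
    field: comorbidity.seizures
    flag_false: true
    provenance: "Aducanumab AUR: seizure disorder"
  - rule_id: no_unstable_psychiatric
    field: comorbidity.unstable_psychiatric
    flag_false: true
    provenance: "Aducanumab AUR: unstable psychiatric illness"
  - rule_id: no_bleeding_disorder
    field: comorbidity.bleeding_disorder
    flag_false: true
    provenance: "Aducanumab AUR: bleeding disorder"
  - rule_id: no_anticoagulants
    field: medication.anticoagulant_use
    flag_false: true
    provenance: "Aducanumab AUR: anticoagulant medication"
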