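# Best-effort operationalization of the lecanemab appropriate use
# recommendations (AUR).  Inclusion largely follows CLARITY-AD; the AUR
# add safety-driven exclusions (notably anticoagulation).
profile_id: aur_lecanemab
description: "Lecanemab appropriate use recommendations: MCI or mild dementia."
amyloid_mode: pet_equivalent
tau_rule_enabled: false
inclusion:
  - rule_id: age_window
    field: age_years
    range: {lo: 50, hi: 90}
    provenance: "Lecanemab AUR: early symptomatic AD age range"
  - rule_id: cdr_stage
    field: cdr_global
    in_set: [0.5, 1]
    provenance: "Lecanemab AUR: MCI or mild dementia"
  - rule_id: mmse_window
    field: mmse
    range: {lo: 22, hi: 30}
    provenance: "Lecanemab AUR: MMSE 22-30"
exclusion:
  - rule_id: no_stroke_or_tia
    field: comorbidity.stroke_or_tia
    flag_false: true
    provenance: "Lecanemab AUR: cerebrovascular event history"
  - rule_id: no_seizures
    field: comorbidity.seizures
    flag_false: true
    provenance: "Lecanemab AUR: seizure disorder"
  - rule_id: no_unstable_psychiatric
    field: comorbidity.unstable_psychiatric
    flag_false: true
    provenance: "Lecanemab AUR: unstable psychiatric illness"
  - rule_id: no_bleeding_disorder
    field: comorbidity.bleeding_disorder
    flag_false: true
    provenance: "Lecanemab AUR: bleeding disorder"
  - rule_id: no_anticoagulants
    field: medication.anticoagulant_use
    flag_false: true
    provenance: "Lecanemab AUR: anticoagulant use strongly discouraged"
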