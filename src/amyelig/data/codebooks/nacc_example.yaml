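# Example NACC-dialect codebook (documentation, not a tested dependency).
# Maps NACC-style column names and numeric missing codes onto the
# canonical schema.  Edit to match the actual extract in use.
clinical:
  columns:
    participant_id: NACCID
    age_years: NACCAGEB
    sex: SEX
    mmse: NACCMMSE
    cdr_global: CDRGLOB
    cdr_memory_box: MEMORY
    etiologic_ad_dx: NACCALZP
    comorbidity.stroke_or_tia: CVHATT
    comorbidity.seizures: SEIZURES
    medication.anticoagulant_use: NACCAC
  values:
    sex: {"1": male, "2": female}
    mmse: {"-4": null, "88": null, "95": null, "96": null, "97": null, "98": null}
    etiologic_ad_dx: {"1": true, "2": true, "3": false, "7": false, "8": null}
    comorbidity.stroke_or_tia: {"0": false, "1": true, "2": true, "9": null}
    comorbidity.seizures: {"0": false, "1": true, "2": true, "9": null}
    medication.anticoagulant_use: {"0": false, "1": true, "-4": null}
neuropath:
  columns:
    participant_id: NACCID
    thal_phase: NPTHAL
    braak_stage: NACCBRAA
    cerad_score: NACCNEUR
    copath.lewy_body: NACCLEWY
    copath.hippocampal_sclerosis: NPHIPSCL
  values:
    thal_phase: {"8": null, "9": null}
    braak_stage: {"7": null, "8": null, "9": null}
    cerad_score: {"8": null, "9": null}
    copath.lewy_body: {"0": absent, "1": present, "2": present, "3": present, "4": present, "8": not_reported, "9": not_reported}
    copath.hippocampal_sclerosis: {"0": absent, "1": present, "2": present, "3": present, "8": not_reported, "9": not_reported}
missing_tokens: ["", "NA", "-4"]
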