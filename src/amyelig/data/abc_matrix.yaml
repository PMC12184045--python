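# ABC staging lookup: A/B/C binnings and the 64-cell summary matrix
# transcribed from the 2012 NIA-AA neuropathologic assessment guideline.
version: "niaa-2012"
a_from_thal: {0: 0, 1: 1, 2: 1, 3: 2, 4: 3, 5: 3}
b_from_braak: {0: 0, 1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}
c_from_cerad: {0: 0, 1: 1, 2: 2, 3: 3}
summary_cells:
  - {a: 0, b: 0, c: 0, level: "not"}
  - {a: 0, b: 0, c: 1, level: "not"}
  - {a: 0, b: 0, c: 2, level: "not"}
  - {a: 0, b: 0, c: 3, level: "not"}
  - {a: 0, b: 1, c: 0, level: "not"}
  - {a: 0, b: 1, c: 1, level: "not"}
  - {a: 0, b: 1, c: 2, level: "not"}
  - {a: 0, b: 1, c: 3, level: "not"}
  - {a: 0, b: 2, c: 0, level: "not"}
  - {a: 0, b: 2, c: 1, level: "not"}
  - {a: 0, b: 2, c: 2, level: "not"}
  - {a: 0, b: 2, c: 3, level: "not"}
  - {a: 0, b: 3, c: 0, level: "not"}
  - {a: 0, b: 3, c: 1, level: "not"}
  - {a: 0, b: 3, c: 2, level: "not"}
  - {a: 0, b: 3, c: 3, level: "not"}
  - {a: 1, b: 0, c: 0, level: "low"}
  - {a: 1, b: 0, c: 1, level: "low"}
  - {a: 1, b: 0, c: 2, level: "low"}
  - {a: 1, b: 0, c: 3, level: "low"}
  - {a: 1, b: 1, c: 0, level: "low"}
  - {a: 1, b: 1, c: 1, level: "low"}
  - {a: 1, b: 1, c: 2, level: "low"}
  - {a: 1, b: 1, c: 3, level: "low"}
  - {a: 1, b: 2, c: 0, level: "low"}
  - {a: 1, b: 2, c: 1, level: "low"}
  - {a: 1, b: 2, c: 2, level: "intermediate"}
  - {a: 1, b: 2, c: 3, level: "intermediate"}
  - {a: 1, b: 3, c: 0, level: "low"}
  - {a: 1, b: 3, c: 1, level: "low"}
  - {a: 1, b: 3, c: 2, level: "intermediate"}
  - {a: 1, b: 3, c: 3, level: "intermediate"}
  - {a: 2, b: 0, c: 0, level: "low"}
  - {a: 2, b: 0, c: 1, level: "low"}
  - {a: 2, b: 0, c: 2, level: "low"}
  - {a: 2, b: 0, c: 3, level: "low"}
  - {a: 2, b: 1, c: 0, level: "low"}
  - {a: 2, b: 1, c: 1, level: "low"}
  - {a: 2, b: 1, c: 2, level: "low"}
  - {a: 2, b: 1, c: 3, level: "low"}
  - {a: 2, b: 2, c: 0, level: "intermediate"}
  - {a: 2, b: 2, c: 1, level: "intermediate"}
  - {a: 2, b: 2, c: 2, level: "intermediate"}
  - {a: 2, b: 2, c: 3, level: "intermediate"}
  - {a: 2, b: 3, c: 0, level: "intermediate"}
  - {a: 2, b: 3, c: 1, level: "intermediate"}
  - {a: 2, b: 3, c: 2, level: "intermediate"}
  - {a: 2, b: 3, c: 3, level: "intermediate"}
  - {a: 3, b: 0, c: 0, level: "low"}
  - {a: 3, b: 0, c: 1, level: "low"}
  - {a: 3, b: 0, c: 2, level: "low"}
  - {a: 3, b: 0, c: 3, level: "low"}
  - {a: 3, b: 1, c: 0, level: "low"}
  - {a: 3, b: 1, c: 1, level: "low"}
  - {a: 3, b: 1, c: 2, level: "low"}
  - {a: 3, b: 1, c: 3, level: "low"}
  - {a: 3, b: 2, c: 0, level: "intermediate"}
  - {a: 3, b: 2, c: 1, level: "intermediate"}
  - {a: 3, b: 2, c: 2, level: "intermediate"}
  - {a: 3, b: 2, c: 3, level: "intermediate"}
  - {a: 3, b: 3, c: 0, level: "intermediate"}
  - {a: 3, b: 3, c: 1, level: "intermediate"}
  - {a: 3, b: 3, c: 2, level: "high"}
  - {a: 3, b: 3, c: 3, level: "high"}
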