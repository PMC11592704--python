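# Default reclassification rules.  A rule fires when its tag set matches a
# variant's evidence tags exactly and the prior class is listed under
# `from`.  `to: null` keeps the class and only attaches a note.
rules:
  - id: ps4_pp3splice_vus_to_lp
    tags: [PS4, PP3_splice]
    from: [VUS]
    to: LP
    note: strong cohort enrichment plus predicted splice donor loss
  - id: ps4_pp3score_vus_to_lp
    tags: [PS4, PP3_score]
    from: [VUS]
    to: LP
    note: strong cohort enrichment plus computational support
  - id: ps4_vus_to_lp
    tags: [PS4]
    from: [VUS]
    to: LP
    note: strong cohort enrichment
  - id: bs_pop_lowrisk_downgrade
    tags: [BS_pop]
    from: [low-risk-LP]
    to: VUS/LB
    note: population frequency inconsistent with elevated monoallelic risk
  - id: pp3_score_watch
    tags: [PP3_score]
    from: [VUS]
    to: null
    note: merits further investigation
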