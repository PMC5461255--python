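# Default calibration of the synthetic battery generator.
#
# Group means and standard deviations of the 13 predictors for the two age
# groups, and the group summaries of the vocoded-speech response (median
# words correct per sentence, 0-7).  Latent loadings place a single general
# cognitive-efficiency factor behind the six predictors the analysis is
# expected to select; reaction-time variables load negatively (low times =
# good performance).  WST carries no loading on the general factor: it is
# the one selected variable expected to surface through the second
# component, and its group-mean pattern (older > young) runs against the
# response, so it is not part of the latent signal set.
n_young: 21
n_old: 20
group_means:
  old:
    TRT: 42.20
    WST: 34.40
    OperationSpan: 41.89
    Verbal_learning: 57.30
    Recall: 1.45
    Recognition: 13.80
    RT_word: 180.25
    RT_freq: 245.65
    CTMT_1_2: -3.00
    CTMT_1_3: 5.80
    CTMT_1_4: -5.00
    CTMT_1_5: 20.95
    Distraction_sensitivity: 28.75
  young:
    TRT: 62.76
    WST: 32.05
    OperationSpan: 59.62
    Verbal_learning: 65.24
    Recall: 0.05
    Recognition: 14.71
    RT_word: 302.86
    RT_freq: 164.10
    CTMT_1_2: 3.71
    CTMT_1_3: 5.02
    CTMT_1_4: 0.23
    CTMT_1_5: 11.04
    Distraction_sensitivity: 20.95
group_sds:
  old:
    TRT: 10.76
    WST: 2.22
    OperationSpan: 17.80
    Verbal_learning: 9.48
    Recall: 2.04
    Recognition: 1.47
    RT_word: 89.84
    RT_freq: 241.06
    CTMT_1_2: 13.39
    CTMT_1_3: 9.58
    CTMT_1_4: 13.10
    CTMT_1_5: 14.75
    Distraction_sensitivity: 8.34
  young:
    TRT: 13.21
    WST: 2.20
    OperationSpan: 9.16
    Verbal_learning: 6.39
    Recall: 0.67
    Recognition: 0.56
    RT_word: 153.20
    RT_freq: 131.98
    CTMT_1_2: 6.37
    CTMT_1_3: 6.16
    CTMT_1_4: 6.83
    CTMT_1_5: 7.86
    Distraction_sensitivity: 6.54
response_means:
  old: 2.5
  young: 4.40
response_sds:
  old: 1.93
  young: 2.26
latent_loadings:
  TRT: 0.80
  WST: 0.0
  OperationSpan: 0.75
  Verbal_learning: 0.70
  Recall: 0.0
  Recognition: 0.65
  RT_word: 0.0
  RT_freq: 0.0
  CTMT_1_2: 0.0
  CTMT_1_3: 0.0
  CTMT_1_4: 0.0
  CTMT_1_5: -0.75
  Distraction_sensitivity: 0.0
response_loading: 0.85
response_bounds: [0.0, 7.0]
floor_mass: 0.15
seed: 0
missing_ospan_old: 0
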