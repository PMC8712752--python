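# Marginal distributions of the matched late-window cohort, by treatment and
# trial-criteria stratum. Ages are mean (SD) truncated to [18, 100]; NIHSS and
# volumes are median [q25, q75]; mRS vectors are the published 3-month
# frequencies (renormalised exactly by the generator).
seed: 20180101
arms:
  evt_defuse3_pos:
    n: 105
    age_mean: 68.0
    age_sd: 15.27
    male_prop: 0.362
    nihss_median: 16
    nihss_iqr: [11, 21]
    core_median: 19
    core_iqr: [8, 36]
    perfusion_median: 112
    perfusion_iqr: [76, 149]
    ica_prop: 0.333
    onset_to_ctp_mean: 322
    onset_to_ctp_sd: 86
    treatment_probs: {EVT_plus_tPA: 0.476, EVT_only: 0.524}
    mrs_90d_probs: [0.1333, 0.1905, 0.1333, 0.2857, 0.1143, 0.0476, 0.0952]
  evt_defuse3_neg:
    n: 26
    age_mean: 70.0
    age_sd: 14.16
    male_prop: 0.308
    nihss_median: 16
    nihss_iqr: [11, 21]
    core_median: 91
    core_iqr: [73, 126]
    perfusion_median: 199
    perfusion_iqr: [162, 229]
    ica_prop: 0.577
    onset_to_ctp_mean: 394
    onset_to_ctp_sd: 72
    treatment_probs: {EVT_plus_tPA: 0.615, EVT_only: 0.385}
    mrs_90d_probs: [0.0769, 0.1154, 0.1154, 0.1923, 0.1154, 0.0385, 0.3462]
  med_defuse3_pos:
    n: 98
    age_mean: 69.9
    age_sd: 13.40
    male_prop: 0.439
    nihss_median: 15
    nihss_iqr: [11, 19]
    core_median: 21
    core_iqr: [11, 46]
    perfusion_median: 113
    perfusion_iqr: [81, 160]
    ica_prop: 0.286
    onset_to_ctp_mean: 403
    onset_to_ctp_sd: 79
    treatment_probs: {tPA_only: 0.071, none: 0.929}
    mrs_90d_probs: [0.1122, 0.1531, 0.102, 0.1327, 0.2755, 0.0816, 0.1429]
  med_defuse3_neg:
    n: 62
    age_mean: 68.0
    age_sd: 13.62
    male_prop: 0.290
    nihss_median: 14
    nihss_iqr: [8, 19]
    core_median: 15
    core_iqr: [0.1, 76]
    perfusion_median: 24
    perfusion_iqr: [7, 151]
    ica_prop: 0.436
    onset_to_ctp_mean: 372
    onset_to_ctp_sd: 83
    treatment_probs: {tPA_only: 0.081, none: 0.919}
    mrs_90d_probs: [0.1935, 0.2097, 0.0323, 0.1452, 0.129, 0.1129, 0.1774]
  evt_dawn_pos:
    n: 91
    age_mean: 65.1
    age_sd: 15.17
    male_prop: 0.429
    nihss_median: 17
    nihss_iqr: [14, 21]
    core_median: 21
    core_iqr: [10, 36]
    perfusion_median: 123
    perfusion_iqr: [86, 150]
    ica_prop: 0.407
    onset_to_ctp_mean: 335
    onset_to_ctp_sd: 94
    treatment_probs: {EVT_plus_tPA: 0.472, EVT_only: 0.528}
    mrs_90d_probs: [0.1648, 0.1319, 0.0989, 0.2198, 0.1209, 0.0659, 0.1978]
  evt_dawn_neg:
    n: 20
    age_mean: 67.3
    age_sd: 17.41
    male_prop: 0.25
    nihss_median: 18
    nihss_iqr: [14, 22]
    core_median: 92
    core_iqr: [82, 128]
    perfusion_median: 207
    perfusion_iqr: [191, 234]
    ica_prop: 0.60
    onset_to_ctp_mean: 387
    onset_to_ctp_sd: 92
    treatment_probs: {EVT_plus_tPA: 0.60, EVT_only: 0.40}
    mrs_90d_probs: [0.10, 0.05, 0.10, 0.20, 0.15, 0.0, 0.40]
  med_dawn_pos:
    n: 59
    age_mean: 69.0
    age_sd: 13.99
    male_prop: 0.407
    nihss_median: 17
    nihss_iqr: [13, 20]
    core_median: 23
    core_iqr: [10, 40]
    perfusion_median: 113
    perfusion_iqr: [75, 137]
    ica_prop: 0.407
    onset_to_ctp_mean: 384
    onset_to_ctp_sd: 73
    treatment_probs: {tPA_only: 0.068, none: 0.932}
    mrs_90d_probs: [0.1525, 0.1186, 0.1017, 0.1525, 0.2034, 0.0678, 0.2034]
  med_dawn_neg:
    n: 35
    age_mean: 69.1
    age_sd: 14.79
    male_prop: 0.371
    nihss_median: 18
    nihss_iqr: [8, 22]
    core_median: 76
    core_iqr: [19, 95]
    perfusion_median: 137
    perfusion_iqr: [104, 196]
    ica_prop: 0.60
    onset_to_ctp_mean: 393
    onset_to_ctp_sd: 81
    treatment_probs: {tPA_only: 0.086, none: 0.914}
    mrs_90d_probs: [0.1143, 0.1143, 0.0286, 0.0857, 0.1143, 0.2571, 0.2857]
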