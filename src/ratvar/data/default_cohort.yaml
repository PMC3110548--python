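# Default 2x2 cohort design: spontaneously hypertensive rats (SHR) with or
# without streptozotocin diabetes (STZ) and with or without renal
# denervation (RD).  Group means/SDs parameterize the per-animal outcome
# distributions; the `cardio` block parameterizes each group's simulated
# beat series.  Sinusoid amplitudes are sqrt(2 * band power) so that a
# group's LF/HF absolute powers are reproduced in expectation; the white
# PI/SAP noise SD absorbs the remaining total variability.  For the
# RD-STZ-SHR systogram the printed LF+HF powers exceed the printed total
# variability (the source summary row is internally inconsistent), so the
# broadband noise SD is floored at 1 mmHg there.
seed: 0
groups:
  SHR:
    diabetes: false
    denervation: false
    n_animals: 7
    outcomes:
      weight_initial_g: {mean: 258.0, sd: 14.0}
      weight_day45_g: {mean: 310.0, sd: 28.0}
      glycemia_initial_mg_dl: {mean: 84.4, sd: 7.0}
      glycemia_day45_mg_dl: {mean: 92.0, sd: 14.0}
      diuresis_ml_24h: {mean: 11.2, sd: 4.0}
      urinary_glucose_mg_24h: {mean: 0.37, sd: 0.4}
      urinary_sodium_meq_24h: {mean: 1.03, sd: 0.3}
      densitometry_au: {mean: 99.9, sd: 14.0}
    albumin_mg_24h: {median: 152.0, lower: 111.0, upper: 341.0}
    cardio:
      hr_bpm: {mean: 384.82, sd: 37.26}
      sap_mmhg: {mean: 178.43, sd: 16.07}
      dap_mmhg: {mean: 141.17, sd: 19.10}
      pi_lf: {freq_hz: 0.64, amp_ms: 3.2156}      # LF power 5.17 ms^2
      pi_hf: {freq_hz: 2.42, amp_ms: 5.3963}      # HF power 14.56 ms^2
      pi_noise_sd_ms: 7.0789                       # total HRV 69.84 ms^2
      sap_lf: {freq_hz: 0.44, amp_mmhg: 6.0811}   # LF power 18.49 mmHg^2
      sap_hf: {freq_hz: 1.72, amp_mmhg: 3.0561}   # HF power 4.67 mmHg^2
      sap_noise_sd_mmhg: 6.7209                    # total SAPV 68.33 mmHg^2
      n_beats: 1000
  RD-SHR:
    diabetes: false
    denervation: true
    n_animals: 6
    outcomes:
      weight_initial_g: {mean: 267.0, sd: 29.0}
      weight_day45_g: {mean: 322.0, sd: 35.0}
      glycemia_initial_mg_dl: {mean: 91.2, sd: 5.0}
      glycemia_day45_mg_dl: {mean: 91.1, sd: 9.0}
      diuresis_ml_24h: {mean: 20.7, sd: 7.0}
      urinary_glucose_mg_24h: {mean: 0.23, sd: 0.4}
      urinary_sodium_meq_24h: {mean: 1.29, sd: 0.8}
      densitometry_au: {mean: 185.6, sd: 13.0}
    albumin_mg_24h: {median: 711.0, lower: 273.0, upper: 1304.0}
    cardio:
      hr_bpm: {mean: 431.32, sd: 36.60}
      sap_mmhg: {mean: 171.03, sd: 5.22}
      dap_mmhg: {mean: 150.27, sd: 13.52}
      pi_lf: {freq_hz: 0.69, amp_ms: 1.8000}      # LF power 1.62 ms^2
      pi_hf: {freq_hz: 2.12, amp_ms: 2.8775}      # HF power 4.14 ms^2
      pi_noise_sd_ms: 7.0704                       # total HRV 55.75 ms^2
      sap_lf: {freq_hz: 0.53, amp_mmhg: 2.7166}   # LF power 3.69 mmHg^2
      sap_hf: {freq_hz: 2.12, amp_mmhg: 10.3866}  # HF power 53.94 mmHg^2
      sap_noise_sd_mmhg: 2.0640                    # total SAPV 61.89 mmHg^2
      n_beats: 1000
  STZ-SHR:
    diabetes: true
    denervation: false
    n_animals: 6
    outcomes:
      weight_initial_g: {mean: 269.0, sd: 13.0}
      weight_day45_g: {mean: 275.0, sd: 53.0}
      glycemia_initial_mg_dl: {mean: 414.1, sd: 135.0}
      glycemia_day45_mg_dl: {mean: 417.5, sd: 114.0}
      diuresis_ml_24h: {mean: 96.9, sd: 42.0}
      urinary_glucose_mg_24h: {mean: 758.0, sd: 544.0}
      urinary_sodium_meq_24h: {mean: 4.38, sd: 2.1}
      densitometry_au: {mean: 182.7, sd: 21.0}
    albumin_mg_24h: {median: 2456.0, lower: 1491.0, upper: 3982.0}
    cardio:
      hr_bpm: {mean: 316.21, sd: 5.17}
      sap_mmhg: {mean: 145.39, sd: 8.49}
      dap_mmhg: {mean: 116.26, sd: 29.34}
      pi_lf: {freq_hz: 0.55, amp_ms: 2.0591}      # LF power 2.12 ms^2
      pi_hf: {freq_hz: 2.00, amp_ms: 8.0137}      # HF power 32.11 ms^2
      pi_noise_sd_ms: 6.2586                       # total HRV 73.40 ms^2
      sap_lf: {freq_hz: 0.36, amp_mmhg: 1.6613}   # LF power 1.38 mmHg^2
      sap_hf: {freq_hz: 1.19, amp_mmhg: 3.3645}   # HF power 5.66 mmHg^2
      sap_noise_sd_mmhg: 2.9275                    # total SAPV 15.61 mmHg^2
      n_beats: 1000
  RD-STZ-SHR:
    diabetes: true
    denervation: true
    n_animals: 5
    outcomes:
      weight_initial_g: {mean: 272.0, sd: 28.0}
      weight_day45_g: {mean: 223.0, sd: 71.0}
      glycemia_initial_mg_dl: {mean: 357.4, sd: 124.0}
      glycemia_day45_mg_dl: {mean: 388.0, sd: 48.0}
      diuresis_ml_24h: {mean: 103.3, sd: 38.0}
      urinary_glucose_mg_24h: {mean: 1019.0, sd: 379.0}
      urinary_sodium_meq_24h: {mean: 4.50, sd: 1.8}
      densitometry_au: {mean: 201.4, sd: 25.0}
    albumin_mg_24h: {median: 1538.0, lower: 667.0, upper: 2988.0}
    cardio:
      hr_bpm: {mean: 363.81, sd: 12.25}
      sap_mmhg: {mean: 157.20, sd: 26.41}
      dap_mmhg: {mean: 118.88, sd: 10.75}
      pi_lf: {freq_hz: 0.54, amp_ms: 3.8419}      # LF power 7.38 ms^2
      pi_hf: {freq_hz: 2.31, amp_ms: 8.6279}      # HF power 37.22 ms^2
      pi_noise_sd_ms: 10.1878                      # total HRV 148.39 ms^2
      sap_lf: {freq_hz: 0.40, amp_mmhg: 10.6404}  # LF power 56.61 mmHg^2
      sap_hf: {freq_hz: 1.52, amp_mmhg: 3.5412}   # HF power 6.27 mmHg^2
      sap_noise_sd_mmhg: 1.0                       # floored; see header note
      n_beats: 1000

# Printed per-group summary rows (mean, SD, n) of the study these defaults
# emulate.  Metabolic rows carry the larger metabolic-cohort n's; the
# cardiovascular rows carry the final cardiovascular n's.  These summaries
# drive the derived-quantity appendix of the report and the summary-based
# ANOVA verification.
reference_summaries:
  weight_initial_g:
    SHR: {mean: 258.0, sd: 14.0, n: 9}
    RD-SHR: {mean: 267.0, sd: 29.0, n: 7}
    STZ-SHR: {mean: 269.0, sd: 13.0, n: 9}
    RD-STZ-SHR: {mean: 272.0, sd: 28.0, n: 5}
  weight_day45_g:
    SHR: {mean: 310.0, sd: 28.0, n: 9}
    RD-SHR: {mean: 322.0, sd: 35.0, n: 7}
    STZ-SHR: {mean: 275.0, sd: 53.0, n: 9}
    RD-STZ-SHR: {mean: 223.0, sd: 71.0, n: 5}
  hr_bpm:
    SHR: {mean: 384.82, sd: 37.26, n: 7}
    RD-SHR: {mean: 431.32, sd: 36.60, n: 6}
    STZ-SHR: {mean: 316.21, sd: 5.17, n: 6}
    RD-STZ-SHR: {mean: 363.81, sd: 12.25, n: 5}
  sapv_mmhg2:
    SHR: {mean: 68.33, sd: 36.16, n: 7}
    RD-SHR: {mean: 61.89, sd: 24.84, n: 6}
    STZ-SHR: {mean: 15.61, sd: 10.26, n: 6}
    RD-STZ-SHR: {mean: 29.86, sd: 20.69, n: 5}
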