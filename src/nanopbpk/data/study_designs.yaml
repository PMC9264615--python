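# Multi-route rat AuNP calibration-study designs (doses in ug, times in h).
# Sizes are particle core diameters; tissue codes are study-table
# abbreviations (Bl blood, Lu lung, Li liver, Sp spleen, Ki kidney,
# GI gastrointestinal tract, Rt remaining tissues, U urine).
designs:
  - route: iv
    sizes_nm: [1.4, 5, 18, 80, 200]
    dose_ug: {1.4: 3.2, 5: 5.3, 18: 10.5, 80: 21.4, 200: 32.9}
    sampling_times_h: [1, 24]
    tissues: [Bl, GI, Lu, Li, Sp, Ki, Rt, U]
    n_replicates: 4
  - route: oral
    sizes_nm: [5, 18, 80, 200]
    dose_ug: {5: 2.6, 18: 8.4, 80: 17.7, 200: 28.8}
    sampling_times_h: [1, 24]
    tissues: [Bl, GI, Lu, Li, Sp, Ki, Rt, U]
    n_replicates: 4
  - route: it
    sizes_nm: [1.4, 5, 18, 80, 200]
    dose_ug: {1.4: 3.0, 5: 6.1, 18: 12.9, 80: 25.6, 200: 40.7}
    sampling_times_h: [1, 3, 24]
    tissues: [Bl, GI, Lu, Li, Sp, Ki, Rt, U]
    n_replicates: 4
  - route: ih
    sizes_nm: [23]
    dose_ug: {23: 20.1}
    sampling_times_h: [2, 4, 24, 168, 672]
    tissues: [Bl, GI, Lu, Li, Sp, Ki, Rt]
    n_replicates: 4
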