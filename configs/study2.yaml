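# Reference design: 4x4 grid, target 20%, 50 single-patient cohorts, weak prior.
theta: 0.20
epsilon: 0.8
cohort_size: 1
n_cohorts: 50
strategy: closest
selection: min_sample_size
constraint: neighbourhood
coherence: false
start_dose: [1, 1]
prior:
  median_grid: study2_medians.csv
  strength: 0.0625   # 1/16
  row_order: b_desc
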