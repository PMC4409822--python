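# Reference design: 6x6 grid, target 30%, 20 cohorts of 2, weak prior.
theta: 0.30
epsilon: 0.8
cohort_size: 2
n_cohorts: 20
strategy: closest
selection: min_sample_size
constraint: neighbourhood
coherence: false
start_dose: [1, 1]
prior:
  median_grid: study1_medians.csv
  strength: 0.027777777777777776   # 1/36: one pseudo-patient spread over the grid
  row_order: b_desc
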