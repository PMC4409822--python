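# pipedesign

Dual-agent phase I dose-escalation design based on products of independent
beta tail probabilities over monotone maximum-tolerated-contour estimates
(the PIPE design), as a reusable library plus a command-line trial
simulator.

Each dose combination on an `I x J` grid carries an independent
`Beta(a_ij, b_ij)` prior on its DLT probability, calibrated from elicited
prior medians and prior strengths. Conjugate updating is closed form; the
maximum tolerated contour at target level `theta` is inferred by scoring
every monotone partition of the grid (there are `C(I+J, I)` of them) with a
product of per-dose beta tail probabilities. Escalation follows the modal
contour through closest/adjacent admissible-dose strategies, dose-skipping
(neighbourhood or non-neighbourhood) constraints, an overdose-probability
safety threshold with early termination, and sample-size-based selection.
At the end of a trial, the experimented doses closest from below to the
final contour are recommended for phase II.

## Layout

| module                   | contents                                                        |
| ------------------------ | --------------------------------------------------------------- |
| `pipedesign.priors`      | beta calibration from median/strength grids, median completion  |
| `pipedesign.contours`    | conjugate updates, contour enumeration/posterior, modal contour, above-contour probabilities, multi-`theta` surface |
| `pipedesign.escalation`  | admissible sets, constraints, coherence, fallback, dose selection, phase II recommendation |
| `pipedesign.scenarios`   | benchmark true-toxicity grids and random monotone scenarios     |
| `pipedesign.simulate`    | single-trial mechanics and Monte-Carlo operating characteristics |
| `pipedesign.io` / `.cli` | grid CSV / YAML config / trial-state files, OC tables, `pipe` CLI |

## CLI

Recommend the next cohort's dose from a design config (and optionally a
trial-state JSON holding accumulated counts):

```sh
pipe next --config configs/study1.yaml --seed 17
pipe next --config configs/study1.yaml --state mytrial.json --seed 17
```

Simulate operating characteristics for a named scenario:

```sh
pipe simulate --scenario table1_s1 --config configs/study1.yaml \
    --n-trials 1000 --seed 17 --out oc.csv
pipe simulate --scenario table2_E --config configs/study2.yaml \
    --n-trials 2000 --seed 17 --style study2
```

`configs/study1.yaml` is the 6x6 reference design (target 30%, 20 cohorts
of 2, weak prior of strength 1/36, neighbourhood constraint, safety
threshold 0.8); `configs/study2.yaml` is the 4x4 single-patient-cohort
design at target 20%. Grid CSVs are oriented with drug B descending by
row (set `row_order: b_asc` to flip).

## Library example

```python
import numpy as np
from pipedesign import (
    PriorSpec, calibrate_grid, DesignOptions, simulate_many, make_scenario,
)

scenario = make_scenario("table1_s1")
prior = calibrate_grid(
    PriorSpec(medians=scenario.truth, strength=1 / 36, theta=0.30)
)
options = DesignOptions(theta=0.30, cohort_size=2, n_cohorts=20)
oc = simulate_many(scenario, options, prior, n_trials=1000, seed=1)
print(oc.experimentation_pct, oc.mean_n_recommended)
```

## Conventions

Doses are 0-based `(i, j)` pairs with `i` indexing drug A and `j` drug B;
toxicity is assumed nondecreasing in both indices. A contour is encoded by
its height vector `h`, where `h[i]` counts the below-contour cells in
column `i`; the above-set is an up-set of the lattice. The interpolation
used to complete partially specified median grids is linear on the
log-odds scale over the dose-index lattice (the choice of scheme is a
documented implementation decision).
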