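# slnbcost

Monte Carlo cost comparison of **sentinel lymph node biopsy (SLNB)** versus
**selective neck dissection (SND)** for early (cT1–2, cN0) oral tongue
squamous cell carcinoma, from a Brazilian public-health perspective (costs
in BRL, R$).

Both procedures stage the clinically negative neck with equivalent
oncological results, so the decision reduces to cost. The package is aimed
at health-economics and head-and-neck-oncology researchers who want a
tested, reproducible implementation of a patient-level decision simulation:
it bundles bottom-up micro-costing with price-index correction, a synthetic
cohort generator calibrated to institutional summary statistics, a
two-probability grid sweep with threshold detection, and population-level
extrapolation from cancer-registry staging counts.

## The model

Each simulated patient is managed under one of two strategies:

* **SND strategy** — upfront neck dissection with the primary resection;
  total cost is a draw from the upfront-SND cost distribution,
  C<sub>upfront</sub>.
* **SLNB strategy** — sentinel node biopsy first. With probability *q* the
  sentinel node is not found and the patient converts to dissection in the
  same admission (cost C<sub>conv</sub>, equal to C<sub>upfront</sub> by
  default). Otherwise, with probability *p* the node harbours occult
  metastasis and a delayed isolated dissection is added
  (C<sub>base</sub> + C<sub>delayed</sub>); with probability 1 − *p* the
  SLNB admission is the only cost (C<sub>base</sub>).

Accounting is by intention to treat: every SLNB-strategy patient
contributes exactly one cost to that arm. The expected per-patient costs
are

```
E[SLNB] = (1 − q)·(μ_base + p·μ_delayed) + q·μ_conv        E[SND] = μ_upfront
```

so at q = 0 the deterministic break-even probability is
p\* = (μ_upfront − μ_base)/μ_delayed. Cost distributions are normals
truncated at zero with the institutional cohort means/SDs (SLNB
5,782.49 / 1,767.17; upfront SND 11,117.25 / 2,033.14; delayed SND
7,620.43 / 1,750.17 BRL); with these coefficients of variation the
truncation shifts the means by under 0.1%.

The two probabilities are swept independently on a grid — *p* from 9% to
100% in 1% steps (the 9.2% floor is the occult-metastasis prevalence
observed in 3,427 pathologically staged registry patients, 316 metastatic),
*q* from 0% to 5.7% in 0.5% steps (the range reported across prospective
trials). Each of the 1,196 cells simulates 1,000 patients per arm and
compares arm means with Welch's t-test at α = 0.05. Along a fixed-*q*
slice two thresholds are read off in increasing *p*: where the SLNB cost
advantage stops being significant, and where upfront SND becomes
significantly cheaper (the cost crossover), each requiring a sustained run
of 3 qualifying cells so single stochastic flips are ignored.

## Worked example

```python
from slnbcost import (default_parameters, expected_strategy_cost,
                      simulate_cell, GridSpec, default_grid, run_grid,
                      find_thresholds)

params = default_parameters()          # p = 316/3427, q = 0, n = 1000/arm
print(expected_strategy_cost(params))  # (6485.16, 11117.25)

cell = simulate_cell(params, seed=1)
# SLNB R$6,440.50 vs SND R$11,130.48; Welch t = -40.4, p = 8.0e-253
# -> direction 'slnb_cheaper': at 9.2% occult metastasis the SLNB-first
#    strategy saves ~R$4,690 per patient, far beyond Monte Carlo noise.

q0 = GridSpec(p_values=default_grid().p_values, q_values=(0.0,))
thr = find_thresholds(run_grid(q0, params, master_seed=1), 0.0, run_length=3)
print(thr.first_nonsignificant_p, thr.first_reversal_p)   # 0.67 0.76
# The advantage is statistically lost at p ~ 67% and reverses at ~76%,
# bracketing the analytic break-even p* = 70.0%.
```

The scripts in `examples/` walk through each capability (micro-costing,
synthetic cohorts and 1:3 matching, single-cell simulation, grid
thresholds, population extrapolation) and print the numbers above.

A full pipeline run — cohorts → grid → thresholds → extrapolation, with a
checksummed artifact manifest — is available from the shell:

```bash
slnbcost run-all --seed 42 --out results/
slnbcost print-config > config.yaml    # fully resolved, self-documenting
```

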