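# Methods

## Decision model

The model compares two neck-management strategies for early (cT1–2, cN0)
oral tongue squamous cell carcinoma under the assumption of equivalent
oncological outcomes, so the comparison is purely monetary. It is a
fixed-transition-probability patient-level simulation: each patient's
pathway is resolved by at most two Bernoulli draws and priced by draws from
event-level cost distributions.

SLNB-strategy pathways and costs:

| pathway | probability | total cost |
|---|---|---|
| sentinel node not found → conversion to SND | q | C_conv |
| node found, occult metastasis → delayed isolated SND | (1−q)·p | C_base + C_delayed |
| node found, negative | (1−q)·(1−p) | C_base |

The SND strategy has a single pathway costing C_upfront. Intention-to-treat
accounting means every SLNB-strategy patient contributes exactly one total
cost to that arm. Closed-form arm expectations
(`expected_strategy_cost`) serve as the analytic oracle for the simulation
and give the deterministic break-even probability at q=0,
p\* = (μ_upfront − μ_base)/μ_delayed = (11,117.25 − 5,782.49)/7,620.43 ≈ 0.700.

## Cost model

Event costs are parameterized from institutional cohort summaries (BRL):
SLNB admission 5,782.49 (SD 1,767.17), upfront SND 11,117.25 (SD 2,033.14),
delayed isolated SND 7,620.43 (SD 1,750.17). Only mean/SD are published, so
the distribution family is a modelling choice: the default is a **normal
truncated at zero whose untruncated parent carries the stated mean/SD**. At
these coefficients of variation (≤ 0.35, i.e. ≥ 2.8 SDs above zero) the
truncation changes the effective mean by far less than 0.1% (verified by a
10⁶-draw test), so the parent parameters can be used directly. A
moment-matched lognormal is available via `cost_family` for sensitivity
analysis, and `sd = 0` degenerates to a point mass.

**Conversion cost.** No separate cost is published for the
sentinel-node-not-found pathway. Since conversion happens in the same
admission as the resection, it is priced with the upfront-SND distribution
by default; any distribution can be supplied via `conversion` in the
config.

**Positive-SLNB cost.** The delayed isolated-SND cohort exists precisely to
price the second admission after a positive sentinel node, so that pathway
costs one SLNB-base draw plus one delayed-SND draw, drawn independently.

Internally costs are floats at full precision; two-digit rounding happens
only at reporting time. The `parse_brl` helper accepts both Brazilian
("5.782,49") and plain ("5782.49") decimal notation.

## Micro-costing

`costing` supports the bottom-up construction of such summaries: itemized
ledgers (category, unit price, quantity, price date) in five categories
(preoperative staging/exams, medical, paramedical, structural,
rehabilitation), with each unit price corrected to a reference period by a
user-supplied general price-index series (monthly `YYYY-MM` keys; the base
period is free, since only index ratios enter). Aggregation is linear and
permutation-invariant; a missing index period or unknown category raises
immediately, identifying the offending item.

## Synthetic cohorts

The generator emulates the three institutional groups (12 SLNB / 36 upfront
SND / 36 delayed SND by default) at the published summaries: cost from the
cohort cost distribution; length of stay and 60-day visit counts from
Poisson laws with rate equal to the printed median (for medians 1, 2, 3 and
8 the Poisson median equals its integer rate, so the printed medians are
matched exactly in expectation); theatre minutes from a truncated normal
centred at the printed median with SD = 15% of the median (the spread is
unpublished; `theatre_cv` exposes it). Age is truncated-normal, gender and
cT Bernoulli at the published fractions. Cost and utilization are
independent by default; `cost_utilization_corr` couples them through a
Gaussian copula on ranks for sensitivity testing, leaving marginals intact.

What the generator does **not** emulate: joint cost–covariate structure,
comorbidity (matching hooks only — the source tabulates none), pathological
detail, or any between-surgeon/centre heterogeneity. Passing parameter
recovery tests therefore shows the pipeline is self-consistent, not that
real patient-level costs follow these families.

1:3 matched pairing mirrors the institutional design: exact gender and cT
match, nearest age, ties broken by lowest patient id (stable), comparators
never reused, and an explicit infeasibility error listing the short strata.

## Grid sweep and thresholds

Default grid: p (occult metastasis) 9%–100% in 1% steps — floored at the
registry prevalence of 9.2% (316/3,427 staged patients) — and q (node not
found) 0%–5.5% in 0.5% steps plus the off-step 5.7% endpoint, the upper
value reported by prospective trials: 92 × 13 = 1,196 cells. Each cell
simulates 1,000 patients per arm ("1,000 simulated patients" is ambiguous
between per-arm and total; per-arm is the default, `n_per_arm` makes the
choice explicit) and compares means with a two-sided t-test. **Welch's
unequal-variance test is the default** — the SLNB arm is a mixture with
p-dependent variance, so pooling is misspecified by construction — with the
pooled Student's t available via `test_method="pooled"` to match the
classical description literally. α = 0.05 (no level is published).

Seeding: each cell draws from an independent `SeedSequence([master_seed,
i, j])` substream keyed by its grid coordinates, so the sweep is
reproducible and cell results are independent of evaluation order. The
full default grid runs in a few seconds on one CPU.

Threshold detection scans a fixed-q slice in increasing p for two events:
the first run of ≥ `run_length` cells that are *not* (significant ∧
SLNB-cheaper) — the onset of non-significance — and the first run of ≥
`run_length` cells that are significant ∧ SND-cheaper — the cost
crossover. `run_length = 3` by default: per-cell significance near the
boundary is a coin flip, so first-occurrence reading (available with
`run_length = 1`) is dominated by noise. Because a reversal run also
qualifies as a non-significance run, the onset can never exceed the
crossover. Thresholds are reported at the grid's 1% resolution without
interpolation. Published threshold readings of ~56% (onset) and ~72%
(crossover) for this model exist; the crossover is compatible with ours
(detected ≈ 74–77% across seeds, just above p\* = 70% as expected, since
detection requires the difference to clear significance). The 56% onset,
however, is **not reproducible from the published parameterization**: with
the cohort SDs at n = 1,000/arm the standard error of the mean difference
is ≈ R$147, so the non-significant band has analytic half-width
1.96·SE/μ_delayed ≈ 3.8 percentage points around p\* — an onset near 66%,
not 56%. The unreported variance assumptions, test variant, and
threshold-reading rule of the original analysis presumably differ; the
package states this openly rather than tuning toward the printed mark, and
its tests assert the ordering and the analytically justified band instead.

### Degenerate inputs

`compare_means` refuses samples with fewer than two values or with zero
variance in both (no test is defined there). When *both* simulated arms
are constant — point-mass costs with degenerate probabilities —
`simulate_cell` treats the comparison as exact instead: p-value 0 and
significant if the constants differ, p-value 1 otherwise. Grid cells
propagate any remaining degeneracy with their (p, q) coordinates attached.

## Population extrapolation

Prevalence is defined on the pathologically staged subset
(316/3,427 = 9.2%); extrapolation multiplies per-patient strategy means by
that subset by default (`staged_only`). The `all_cT12` scope scales to all
8,802 clinical T1–2 patients under the assumption that the prevalence
transports, and flags that assumption in its output. The percent reduction
is 100·(E[SND] − E[SLNB])/E[SND] ≈ 41.7% at the baseline prevalence. A
published population reduction *range* (27.93%–66.54%) has no recoverable
derivation; the package reports its own clearly labelled reconstruction —
`reduction_range` evaluates the reduction at mean ± 1 SD per-patient cost
bounds of each simulated arm, pairing pessimistic with optimistic bounds —
which brackets the point estimate and overlaps the published interval, but
is not expected to reproduce its endpoints.

## Pipeline and reproducibility

A single validated YAML config (unknown keys rejected, every nested
invariant checked at load) drives `run_pipeline`: cohorts → grid →
per-slice thresholds (headline slice q = 0) → extrapolation, all outputs
plain CSV/JSON plus an optional cost-vs-p figure with the non-significance
band shaded. A manifest records a SHA-256 checksum per artifact; manifests
are a pure function of (config, master seed) — no timestamps enter any
output.

## Problem sizes in the test suite

Unit and property tests run at small n; distributional checks use 10⁶
draws where a closed-form standard error is the oracle; cohort recovery
uses n = 10,000 over 20 seeds; threshold checks run the 92-cell q = 0
slice over 5 seeds and the full 1,196-cell grid over 3 seeds; type-I-error
calibration uses 3,000 null cells. The whole suite completes in about a
minute on one CPU.

## Known limitations

* Fixed transition probabilities: no time-dependence of recurrence risk,
  no survival or quality-of-life modelling, no discounting, no ICERs —
  the comparison is cost-only under assumed outcome equivalence.
* Adjuvant-therapy costs are out of scope (they depend on pathology, not
  on the staging procedure), as is any link to live price databases.
* Single-institution cost parameters; the synthetic cohorts inherit every
  simplification listed above, so agreement with them bounds internal
  consistency only.
* Two published headline values are knowingly not reproduced: the 56%
  onset (see above) and the 27.93%–66.54% reduction-range endpoints
  (derivation unrecoverable); both are replaced by stated, testable
  properties.
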