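# Methods

## Model structure

The model is an annual-cycle Markov cohort model for advanced primary open
angle glaucoma, run separately for two strategies: primary trabeculectomy
and medical treatment. Both eyes are modelled independently on an ordered
per-eye severity scale — by default `advanced`, `severe`, `end_stage`,
`blind` — and the cohort occupies combined states `(index eye, fellow eye)`
plus a single absorbing death state (17 states for the 4-level default).
The scale is configurable; the 4-level default is a modelling choice, not a
replication of any particular staging worksheet. Disease is irreversible:
an eye never improves and never skips a level within a cycle, so all
transition mass flows toward more severe combined states.

Three conventions are fixed and documented rather than exposed as options:

- **Competing risks within a cycle:** death is applied first, at the
  life-table probability for the cohort's current age (sexes mixed by a
  weighted average of qx), adjusted for blindness; survivors then progress.
- **Joint eye moves:** the two eyes progress independently, so a cycle in
  which both eyes worsen carries the product of the per-eye probabilities.
  Whether simultaneous two-eye progression should be allowed at all is a
  genuine modelling choice; product independence is the simplest
  assumption consistent with modelling the eyes independently.
- **Blindness and mortality:** the death probability becomes
  `1 − (1−q)^SMR`, with the SMR chosen by blindness status (1 with no blind
  eye, `smr_unilateral` with one, `smr_bilateral` with both). SMRs below 1
  are rejected. Both default to 1.0 — no excess mortality — because no
  defensible default magnitude exists; users supply their own.

The lifetime horizon is operationalised through the life table, which must
close with qx = 1 at a terminal age; the trace is run until that age, at
which point the cohort is fully absorbed. The bundled life table is a
synthetic Gompertz curve (`make_gompertz_life_table`, qx ≈ 1% at 65 and 8%
at 85 for men, women scaled by 0.75, terminal age 110), declared synthetic
and trivially replaceable by a national table in the same (age, sex, qx)
CSV format.

## Payoffs

Annual state costs and utilities come from ordinary least squares
regressions of the trial outcomes on severity-level indicators plus a
treatment indicator. Utilities are keyed to the **better** eye — vision-
related quality of life follows the better-seeing eye — while costs are
keyed to the **worse** eye, on the argument that treatment intensity
follows the more diseased eye. Regression predictions, not raw cell means,
fill every (combined state, arm) cell, which is what lets the model
extrapolate to severity states rarely or never observed during trial
follow-up. Utility predictions above 1 are clamped to 1 (logged); negative
cost predictions are clamped to 0. Three utility instruments are carried in
parallel (EQ-5D-5L, HUI-3 and a glaucoma-specific index), each entering the
model only as a per-state number.

QALYs and costs accrue at cycle start, discounted at 3.5% per annum (the UK
reference rate) with factor `(1+d)^−t`; a half-cycle-correction switch
(average of adjacent occupancy rows) is provided to quantify the impact of
that convention, and is off by default. The ICER is reported as `undefined`
when ΔQALY = 0 and as a dominance verdict when the signs disagree, rather
than as ±∞.

## Estimation

Transition probabilities use a constant-hazard (exponential) time-to-event
model, one hazard per adjacent severity pair per arm — the memoryless
family that matches the annual-cycle Markov assumption. From annual
inspection data the estimator counts, per arm and pair, the eye-intervals
at risk and the progression events, with actuarial exposure (a progressing
eye contributes half an interval): `rate = events / eye-years`, converted
by `p = 1 − exp(−rate)`. The naive whole-interval exposure would bias the
hazard downward by roughly `p/2` relative to the truth, a bias several
standard errors wide at realistic trial sizes; the actuarial convention
removes almost all of it. Standard errors follow the square-root-of-events
rule on the rate scale, delta-propagated to the probability scale.
Zero-event transitions get probability 0 with a `wide_uncertainty` flag
rather than a fabricated interval. An alternative estimator fits the
annual progression indicator on the logit scale (intercept-only logistic
regression, i.e. the observed annual proportion) behind
`method="logistic"`; the exponential route is the default because it also
yields the rates needed if the cycle length were changed.

## Synthetic trial generator

The generator emulates the data structure the estimation stage assumes: two
randomized arms with exact allocation, baseline ages ~N(67, 8²) truncated
to the life table, 30% female, an index eye entering at advanced disease or
worse, annual visits for 5 years, unidirectional per-eye progression with
probability `1 − exp(−hazard)`, gamma-distributed annual costs (right-
skewed), beta-distributed utilities, death simulated from the same
life-table + SMR machinery as the model, and optional independent
missingness of post-baseline records. Defaults (all overridable in
`TrialConfig`):

| parameter | default | rationale |
|---|---|---|
| participants | 1000 | mid-size pragmatic surgical trial; large enough that every transition is observed |
| follow-up | 5 years | enough eye-years to estimate late transitions; 2-year data leave them event-free |
| hazards (med) | 0.10 / 0.10 / 0.08 per eye-year | slow treated progression (~1 level per decade) |
| hazards (trab) | 0.06 / 0.06 / 0.05 | surgery slows progression by ~40% |
| cost (med) | £600–1200/yr by worse-eye level | rising monitoring/treatment burden |
| cost (trab) | medication + £300 at every level | additive arm effect, matching the regression's form |
| utilities | e.g. EQ-5D 0.80→0.48 by better-eye level | steeper for the vision-sensitive HUI-3, flatter for the condition-specific index |
| cost SE | 30% of mean; utility SE 0.12 | realistic skew/noise |
| entry states | index (0.80, 0.12, 0.05, 0.03); fellow = max(index, draw) | index eye is the less severe eligible eye by construction; a small bilateral-blind mass keeps every severity level observable |

The generator is a pure function of its config (one seed, split into
deterministic child streams per stage). It deliberately omits features of
real trial data: no interval censoring (visits at exact year boundaries),
no treatment crossover or further surgery, no adverse events, no
informative dropout, and arm effects that are exactly additive on the
regression scale. Passing tests therefore demonstrate internal statistical
correctness — parameter recovery, trace/microsimulation agreement,
reporting arithmetic — not that any particular clinical result is
reproduced.

## Sensitivity analysis

PSA draws: beta per transition probability (method of moments from its
probability-scale SE — the fallback used because the exponential estimator
carries no coefficient covariance), and one multinormal block per payoff
regression, drawn via the Cholesky factor of the OLS covariance so severity
and treatment effects stay correlated; drawn coefficients are pushed
through the payoff predictions, re-applying the clamps. Covariances that
are not positive semi-definite after symmetrisation fail loudly with the
block named. Each iteration reruns both arms' traces; all horizon ×
instrument cells share the same draws. Iterations use independently
spawned child streams of one seed, so runs are bit-reproducible and single
iterations can be replayed. The conventional iteration count is 10 000;
the packaged default configuration uses 2000, which puts the Monte-Carlo
error on a CEAC probability near one percentage point while keeping the
default pipeline fast.

CEAC: `P(cost-effective at λ) = P(λ·ΔQALY − ΔCost > 0)`, ties counted for
the incumbent (medication); the two arms' probabilities sum to 1 by
construction. The λ grid runs 0–50 000 in steps of 500 and always contains
the reporting thresholds {0, 10 000, 20 000, 50 000}. The CE plane fits a
bivariate normal to (ΔQALY, ΔCost) with a chi-square(2) 95% radius;
rank-deficient clouds are flagged degenerate instead of producing a fake
ellipse.

One-way analysis reruns the deterministic model at the two bounds of a
single parameter (default outcome: incremental NMB at £20 000/QALY).
Default ranges are a convention, stated as such: ±20% of base value,
except the discount rate (0–7%), SMRs (bounded below by 1) and utility
scale (±10%, clamped so no utility exceeds 1). Every scalar in a ParamSet
is addressable by a path string (`discount_rate`,
`transition/<arm>/<level>`, `payoff/<outcome>/<state>/<arm>`, …), plus two
whole-schedule multipliers (`cost_scale`, `utility_scale/<instrument>`)
for tornado bars that move a whole cost or utility schedule at once.

## Numerical choices

Row stochasticity of every transition matrix is asserted at 1e-9; the
engine builds each arm's survivor-conditional progression block once and
recombines it with the age-specific adjusted death vector each cycle.
Probability/rate conversions use `expm1`/`log1p` for accuracy near zero.
`rate_to_prob`/`prob_to_rate` are exact inverses; gamma and beta
method-of-moments conversions reproduce their input moments exactly. Beta
and gamma draws with SE = 0 degenerate to point masses. PSA probability
draws are clipped to [0, 1]; per-eye adjacent-transition parameterisation
keeps matrix rows stochastic without renormalisation.

## Testing strategy and problem sizes

The suite checks closed forms (discounting, SMR adjustment, single-row
matrix entries), invariants as property tests (monotone severity, row
sums, monotone death, CEAC complementarity, NMB/ICER decision agreement),
and statistical correctness against independent oracles: the cohort trace
against a 200 000-individual microsimulation (cells agree within binomial
SEs; excursions beyond 3 SE cluster because paths are correlated across
cycles, so a small fraction is allowed and everything is bounded at 6 SE),
hazard/cost/utility recovery on 2000-participant trials with ≥90%
coverage of 95% intervals per quantity over 50 replications, and CEAC
fractions against brute-force enumeration. The packaged default pipeline
(simulate → estimate → run → PSA 2000 → report) completes in well under a
minute on a single CPU.

## Known limitations

- Mortality affects nothing but state occupancy; there is no
  severity-specific mortality beyond the blindness SMRs.
- No treatment switching, repeat surgery, cataract states or tunnel
  states; the strategies are fixed at entry.
- The transition estimator assumes constant hazards; time-varying
  progression would need a different family and age-indexed matrices.
- Transition uncertainty enters the PSA as independent betas, not jointly
  with the payoff coefficients; cross-parameter correlation is carried
  only within each regression block.
- The synthetic generator's simplifications (above) mean quantitative
  outputs under default conditions characterise the method, not any real
  patient population.
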