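# Methods

## Scope and data model

`nutricea` reproduces, as reusable components, the analytic chain of a
three-arm comparison of enteral nutrition support strategies (PEG
gastrostomy, nasogastric tube feeding, oral supplements) during
definitive chemoradiotherapy for esophageal squamous cell carcinoma.  No
patient-level data are distributed: the synthetic-cohort module generates
patient records whose summary statistics match the published group-level
tables, and every downstream stage (trial statistics, propensity
matching, Markov cost-effectiveness model) consumes those records or the
published aggregates directly.

## Synthetic cohort generator

Each arm is described by an `ArmProfile` holding the published group
summaries: n = 63 per arm; weight-change mean ± SD (−1.4 ± 4.4%,
−2.1 ± 3.3%, −3.0 ± 5.4% for PEG/NTF/ONS); gain/unchanged/loss category
counts; albumin ≥ 35 g/L, CRP < 15 mg/L and lymphocyte ≥ 1.0×10⁹/L
proportions; CR/PR/SD/PD response counts; 1-year LRFS (0.883 / 0.786 /
0.768) and OS (0.886 / 0.831 / 0.812); itemized mean costs in USD
(converted at 6.37 CNY/USD) and mean hospital days.

**Event times.**  Progression and death are competing exponentials with
constant hazards fitted in closed form: the death hazard is
λ_D = −ln S_OS(1) and the progression hazard λ_P = ln(S_OS(1)/S_LRFS(1)),
so the progression-free time min(T_P, T_D) has 1-year survival equal to
the published LRFS and the death margin equals the published OS.  The
exponential law is the minimal assumption given that only 1-year rates
are published.  Administrative censoring is applied at a 3-year horizon,
matching the roughly 31.7-month maximum follow-up.  By construction
OS time ≥ progression-free time for every subject.

**Weight change.**  The three-level weight category (gain / unchanged /
loss) is drawn from the published multinomial; the continuous percent
change is then drawn from a latent normal truncated to the category's
region, with "unchanged" defined as ±1% (the source tables define no
tolerance; ±1% is this package's convention).  The latent (μ*, σ*) are
*not* the published moments: because the published category weights
differ from the latent normal's own region masses, plugging the published
mean/SD into the truncated components would bias the mixture mean (for
the PEG arm, to −1.73% instead of −1.4%).  Instead (μ*, σ*) solve the
two-equation system requiring the category-weighted truncated-normal
mixture to have exactly the published mean and SD (for PEG:
μ* = −0.260, σ* = 4.407).  Generated cohorts therefore reproduce both
the category frequencies and the moments.

**Costs and ancillary variables.**  Cost items and hospital days are
gamma-distributed with the published means and a coefficient of variation
of 0.3 (not published; a typical dispersion for itemized hospital costs).
A `hospitalization_other` item absorbs the difference between the
published 6-month total and the published itemized costs, so item means
sum to the published totals.  Ages are uniform over the published range;
sex, stage and ECOG are drawn from the published proportions (stored as
counts out of 63, so generated proportions are exact fractions).

**Reproducibility.**  A cohort is a pure function of (profile, seed,
horizon).  Multi-arm trials derive per-arm sub-seeds from the master seed
and a CRC-32 of the arm label, so permuting the arm order never changes
any arm's records.

What the generator does *not* emulate: covariate–outcome correlation
within arms (weight change, response and survival are drawn
independently given the arm), time-varying hazards, and informative
censoring.  Tests passing on these cohorts therefore validate the
*computational* chain, not clinical associations beyond the group
margins.

## Trial statistics

The design-stage sample size is the smallest n for which the exact
noncentral-*t* power of a one-sided one-sample t-test reaches 0.80 at
α = 0.025 for the standardized effect (5 − 3)/5 = 0.4; the power at
n = 51 is 0.7999 and at n = 52 is 0.8078, giving 52.  A closed-form
normal approximation ⌈((z₀.₉₇₅ + z₀.₈)/0.4)²⌉ = 50 is provided as a
cross-check; the exact answer exceeds it by 1–2 as expected from the
heavier t tails.  Planned enrollment inflates by ⌈n/(1 − dropout)⌉,
giving 62 at 15% dropout.

Kaplan–Meier estimation is delegated to `lifelines`; the wrapper exposes
the product-limit table and a right-continuous step evaluator (the value
*at* an event time is the post-jump value).  Group comparisons use
classical one-way ANOVA for continuous outcomes and the Pearson
chi-square without continuity correction for categorical ones —
on the published 3×3 weight-category table this gives χ² = 18.74,
p = 0.00088, matching the published p = 0.001.  Categories unobserved in
every arm are dropped before testing.  No test is attempted for the
published survival p-values, whose underlying test is not identified.

## Propensity matching

Arm-membership probabilities come from a multinomial logit
(`statsmodels.MNLogit`, Newton iterations to gradient tolerance 1e-8,
with an L-BFGS fallback when Newton diverges).  Continuous covariates
are standardized inside the design matrix so that coefficients live on
the logit scale; under (quasi-)separation — e.g. a stage level absent
from one arm — coefficient magnitudes are capped at ±15 with a warning,
preserving finite logits.

The binary convention "match on the logit of the propensity score" has
no unique three-group analogue.  This package matches on the logit of
the *reference-arm* (PEG) membership probability, with the caliper set
to 0.6 times the pooled SD of that scalar — the closest scalar
generalization of the binary rule; whether the original analysis used
one logit or a vector is unknown, so this choice is documented rather
than inferred.  Matching is greedy 1:1:1 nearest-neighbor without
replacement: reference subjects are processed in ascending order of
their worst-case nearest-candidate distance (a deterministic order;
a seeded shuffle breaks exact ties), and a triplet is kept only when
the nearest unused candidate in *both* other arms lies within the
caliper.

Balance diagnostics report standardized mean differences for continuous
covariates and raw proportion differences for categorical levels (a
level absent from one arm would otherwise produce an unbounded
standardized difference).  With 63-subject matched groups the sampling
SE of an SMD is ≈ √(2/63) ≈ 0.18, so individual post-matching SMDs
fluctuate around ±0.3 even under perfect balance; the test suite
therefore checks that matching *reduces* mean absolute imbalance from
oversized candidate pools rather than imposing a hard per-covariate cap.

## Markov cohort model

Three states — disease-free, relapse, death — with annual cycles.  The
disease-free row of the annual transition matrix is calibrated from the
observed rates: p(DF→DF) = S_LRFS(1); p(DF→death) combines 1 − S_OS(1)
with a constant background mortality (default 0.01/year) as
1 − (1 − p₁)(1 − p₂), capped at 1 − S_LRFS(1) so the row stays
stochastic; relapse takes the remainder.  Because the published PEG
rates leave only a 0.3% relapse margin, the default background
mortality absorbs it and the PEG disease-free row has zero relapse
probability — a documented consequence of calibrating to rates in which
OS already counts all-cause death.  Post-relapse mortality defaults to
0.5/year (median post-relapse survival ≈ 1 year, configurable; the
original model's parameter table is not available).

Rewards use state membership at cycle start with no half-cycle
correction; cycle-t costs and QALYs are discounted by (1.03)^(−t); the
one-time treatment cost (the observed 6-month total per strategy) enters
undiscounted at t = 0.  "Lifetime" is operationalized as 38 annual
cycles (median age 62 to age 100), with early stop once the alive
fraction falls below 1e-6.  Utilities are 0.80 (disease-free), 0.53
(relapse), 0 (death); annual state costs default to $500 follow-up
(disease-free) and $8,000 relapse management.

The engine is verified three ways: closed-form geometric series for
absorbing states (1e-9), the matrix-power identity occupancy(t) =
init·Pᵗ, and an independent 10⁵-trajectory per-individual
microsimulation (agreement within 3 Monte-Carlo standard errors).

Because the original model's parameter table (costs per state,
distributions) is unavailable, absolute per-strategy lifetime totals are
*not* reproduction targets.  Under the shipped configuration — whose
one-time costs are the published 6-month totals, under which the PEG arm
is both cheapest and most effective — the default frontier reduces to
PEG dominating both comparators; the published frontier, in which PEG is
the most costly strategy, evidently reflects unavailable long-term cost
inputs.  Frontier arithmetic itself is exercised on the published
(cost, QALY) triples, reproducing the sequential ICERs to within the
rounding of the printed inputs (1769.81 and 3452.94 from rounded inputs
vs 1766.82 and 3457.65 printed).

## Cost-effectiveness toolkit

The efficiency frontier sorts strategies by cost, removes strongly
dominated strategies (no cheaper-or-equal strategy with at least as many
QALYs), then iteratively removes extendedly dominated ones until
sequential ICERs strictly increase.  Exact cost-and-QALY ties are broken
by label order and flagged.  Frontier membership is tested against an
independent brute-force oracle: a strategy is on the frontier iff it
uniquely maximizes NMB(λ) on some interval, probed at midpoints between
all pairwise incremental-ratio breakpoints.

One-way sensitivity recomputes the pairwise ICER at both bounds of each
parameter (all else at base), addressing parameters by path
(`one_time_cost`, `utilities.<state>`, `state_costs.<state>`,
`transitions.<from>.<to>`, optionally prefixed by a strategy label);
setting an off-diagonal transition rebalances the row's stay
probability.  Rows are sorted by descending ICER swing (tornado order).

PSA samples beta distributions for probabilities and utilities
(method-of-moments from the mean and a 10% relative SD) and gamma
distributions for costs (30% relative SD) — the original distribution
table being unavailable, these defaults are configurable.  One uniform
draw per parameter per iteration is shared across strategies (common
random numbers), so between-strategy contrasts are not inflated by
sampling noise; sampled transition rows pushed outside [0, 1] are
renormalized and counted.  CEACs report, at each willingness-to-pay on a
$0–50,000 grid (step $5,000), the fraction of 10,000 draws in which each
strategy maximizes NMB; rows sum to 1 by construction.  The
acceptability report interpolates the curves at the headline thresholds
($10,000 and $50,000/QALY) and flags the preferred strategy at the
$33,962/QALY cost-effectiveness threshold (three times 2020 GDP per
capita in China).  Published acceptability probabilities (77.7% etc.)
depend on the unavailable distribution table and are not reproduction
targets.

## Numerical and testing choices

- Seeds: every stochastic routine takes an explicit seed; PSA and
  matching are bit-reproducible given (inputs, seed).
- The latent weight-change calibration solves its 2×2 system with
  `scipy.optimize.fsolve` (residual < 1e-6 enforced, typically ~1e-15)
  and caches the solution per profile.
- Problem sizes in the test suite: moment/goodness-of-fit checks use
  10⁴–10⁵ generated subjects; microsimulation oracles use 10⁵
  trajectories; frontier–oracle agreement uses 100–150 random 5-strategy
  instances; PSA tests use 10²–10³ draws (the shipped default remains
  10,000).
- Degenerate inputs: survival probability 1 yields all-censored cohorts
  rather than an error; a zero-SD logit sets the caliper to +∞ (all
  pairings admissible); chi-square on identical distributions returns
  statistic 0, p = 1 exactly.

## Known limitations

- Within-arm independence of outcomes means the synthetic cohorts cannot
  support analyses of covariate–outcome association.
- The scalar (reference-arm logit) matching distance controls balance
  against the reference arm; balance between the two comparator arms is
  only indirect.
- Constant hazards and a constant background mortality are simplifications;
  age-dependent life tables are not used.
- Absolute cost/QALY totals depend on state-cost and relapse-mortality
  defaults chosen here and should be re-parameterized for any real
  application.
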