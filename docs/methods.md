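# Methods

`panelbench` is a simulation laboratory for a survey-comparison design:
several nonprobability quota-sampled web-panel surveys and one
probability-sample survey are fielded "in parallel" on a synthetic
population, and each is judged against benchmarks by an odds-ratio battery.
Because the population is synthetic, the size and direction of every
selection bias is known exactly, so the comparison machinery itself — quota
construction, variable selection, weighting, OR summaries, bootstrap
inference, the cross-panel consistency test — can be validated end to end.

## The synthetic population

Individuals carry categorical covariates (sex; age group 18-24/25-34/35-44;
region; partnership status; age finished full-time education; any under-18s
in the household; household size; drinking frequency; smoking; tenure; two
attitude items; plus benchmark-only variables such as ethnicity, general
health, driving licence and sexual identity). Covariates are drawn
independently from declared marginals, except where a *joint block* declares
an explicit joint table (the default scenario couples age finished education
with economic activity, since those two are strongly associated in real
populations and exercise the collinearity rule in variable selection).
Everything is defined on a finite category grid, so exact enumeration —
summing over cells weighted by their joint probability — is always available
as an oracle.

Outcomes are ~35 survey questions tagged by administration mode (CAPI:
interviewer-administered; CASI: self-completed) and type (behavior /
opinion):

* binary behaviors: `logit P(Y=1) = a + x'b`, intercepts spanning rare
  (~3%) to common (~50%) prevalences;
* 5-point opinion items: proportional odds,
  `logit P(Y<=k) = alpha_k − x'b`, with category 3 the neutral midpoint
  ("neither agree nor disagree").

Outcomes are conditionally independent given covariates; an optional shared
person-level latent logit offset (`latent_sd`, default 0) induces
within-person correlation where the consistency test needs it. The
default-battery coefficients are assigned once from a fixed internal seed —
they are part of the frozen study condition, not a per-run draw.

Two propensities complete each record:

* `p_respond` — probability-survey participation, a logistic model in the
  covariates. Probability sampling is independent Bernoulli with inclusion
  probability proportional to `p_respond`, rescaled to the target size.
  The real benchmark survey's stratified clustered design is *not*
  simulated: design effects are orthogonal to the comparison machinery
  under test, and no estimation step assumes clustering.
* `p_join` — volunteer-panel membership. The joining model may include
  outcome terms directly, planting *non-ignorable* selection bias (people
  join partly because of what they would answer); the default scenario puts
  a log-odds of 0.5 on one sensitive CASI behavior, alongside covariate
  effects (younger, more educated, London, frequent drinkers over-join).

What the generator does **not** emulate: mode-specific measurement error
(CAPI vs CASI vs web reporting differences), interviewer effects, panel
attrition or conditioning. Mode is a tag, not a data-generating mechanism —
the real study could not separate selection from mode effects, and the
generator deliberately plants only selection bias, so a passing test here
says nothing about measurement differences in real data.

## Quota sampling

Quota targets per grouping (age within sex, partnership within sex, region
marginal, plus any modification variables) are benchmark proportions times
the total target, integerised by the largest-remainder rule so each
grouping sums exactly to the total. Panel members stream in seeded random
order; a member is accepted iff every quota cell they fall into is under
target. When the stream exhausts short of the total, the unfilled cell with
the largest absolute shortfall is *released*: its unmet shortfall becomes
transferable slack for its grouping, so full sibling cells may overfill by
at most that amount, and the remaining members are re-streamed in a fresh
seeded order (re-invitation waves). This policy is deterministic and fully
audited in the relaxation log. The rationale: a cap released on an
*unfillable* cell would not bind — the members still arriving are blocked by
the full sibling cells — so the release must transfer the deficit to the
cells that can still absorb it. That reproduces the field outcome reported
for such surveys: totals met, composition off in the deficient categories.

The omnibus pre-screen flags a random subset of the panel as having the
modification variables observed in advance; unflagged members are screened
at survey entry and rejected without outcomes if their cell is full.

## Quota-modification variable selection

* **Stepwise membership selection** (used for the first modified survey):
  stack the probability sample with a basic web survey, regress the
  membership indicator on candidate variables by forward stepwise logistic
  regression. Entry is by likelihood-ratio test (chosen over Wald for
  stability at moderate n; categorical candidates enter as whole dummy
  blocks, the block LRT governing entry), threshold `alpha`, no
  AIC/BIC stopping. Afterwards a collinearity rule runs: if two entered
  variables have Cramér's V > 0.5, the one with the larger entry p-value is
  dropped. By default the model does not condition on the basic quota
  variables (a `condition_on` argument adds them).
* **Bivariate screen** (shortlisting omnibus questions): each candidate is
  scored by the number of key outcomes with which it is associated both
  marginally and after adjusting for age group, partnership status and
  region (logistic for binary outcomes, proportional odds for ordinal);
  candidates are ranked by that count.
* **Omnibus membership selection**: the stepwise procedure with the
  panel-omnibus respondents as the second stratum.

## Weighting

Every survey is poststratified to the census-analog margins for age group
within sex: weight = target share / weighted sample share per cell,
rescaled to mean 1. Empty cells with nonzero targets are a hard error (no
collapsing). The probability sample is additionally raked to a region
margin by iterative proportional fitting (converged when the maximum
relative weight change in a cycle is below 1e-10); web surveys are not
weighted by region. No trimming is applied (a cap argument exists but is
off by default). No propensity-score or covariate-calibration adjustment is
in scope.

## Odds-ratio battery

Against an **aggregate benchmark** (census-style margin), the OR is the
cross-product of the survey's weighted proportion against the fixed
benchmark proportion. The benchmark is treated as a known constant —
benchmark sources are one to two orders of magnitude larger than the
surveys — so the log-OR variance is survey-side only, `1/(n_eff p(1-p))` by
the delta method with the Kish effective size `n_eff = (Σw)²/Σw²`.
Boundary proportions error unless a continuity flag adds 0.5 to each
implied cell.

Against a **microdata benchmark** (the probability survey), the OR comes
from a weighted regression of the outcome on a survey-membership indicator:
binary outcomes by weighted logistic regression — for this saturated
two-group model the MLE equals the weighted 2×2 cross-product ratio and is
computed in closed form — and ordinal outcomes by a weighted
proportional-odds model fitted by BFGS with analytic gradients. Both use a
probability-weight sandwich variance `A⁻¹BA⁻¹` with `B = Σ wᵢ² sᵢsᵢ'`. A
proportional-odds fit failure falls back to the outcome's declared binary
split with a warning; the proportionality assumption itself is not tested,
matching the single-OR-per-ordinal-outcome reporting convention.
Non-ordered categorical variables are reduced to a declared binary split to
avoid multiple ORs per variable.

Summaries per outcome group (all; behavior/opinion × CAPI/CASI; computed
separately by sex): the unweighted mean and maximum of the absolute OR
`max(OR, 1/OR)`, and the count of outcomes with p < 0.05 — deliberately
with **no** multiple-testing adjustment, matching the reporting convention
the battery replicates.

### Bootstrap and the difference test

The bootstrap SE of an average absolute OR resamples participants with
replacement independently within each survey (sizes preserved, B = 100 by
default), re-poststratifies each replicate, recomputes every OR with the
benchmark held fixed, and takes the SD of the replicate averages. Within
replicates the proportional-odds refit uses the sufficient statistics
(weight totals per category × survey cell), which is exact for a single
binary regressor and makes B = 100 cheap. An OR that cannot be computed in
a replicate (degenerate resample) is dropped from that replicate's average;
if more than 10% of replicates are affected the SE is flagged unreliable.
Two basic surveys are "combined" by pooling the samples with jointly
rescaled weights (primary reading); averaging the two surveys' per-outcome
absolute ORs is available as `method="average"`.

Differences in average absolute ORs are tested by
`z = (ā − b̄)/√(se_a² + se_b²)` under normality. **Known limitation**: under
an exact null (every true OR = 1) this test is conservative — the fold at
1 makes the bootstrap SE overestimate the sampling SD of the average (the
statistic is bounded below by 1 and not normal), and the realised
rejection rate is well below the nominal 5%. Away from the null (true ORs
clearly off 1, the regime the comparison is designed for) the bootstrap SE
tracks the empirical SD closely (validated to within 25%).

## Cross-panel consistency (GEE)

Two panel surveys sharing a question battery are stacked into long format
(person × question × binary response; ordinal items pass through their
declared binary split). A logit marginal model with question fixed effects
and survey terms is estimated with an independence working correlation —
whose point estimates coincide with pooled logistic ML — and a sandwich
variance clustered on person, which keeps inference valid under arbitrary
within-person correlation. Three outputs: per-question survey effects, a
single common survey effect from the main-effect-only model, and the joint
Wald test that all per-question survey effects are zero (the primary
consistency test). Weights are not used by default (the comparison is
between the panels' raw responses); `use_weights=True` enables weighted
estimating equations.

## Seeds and determinism

Every stage draws from a child seed split off the master seed with
`numpy.random.SeedSequence.spawn`, so stages are independently
reproducible and a rerun with the same master seed yields a byte-identical
report bundle (no timestamps are written).

## Problem sizes used in the validation suite

The test suite validates each claim at the smallest size that gives clean
Monte-Carlo resolution: calibration checks use 500 replicates (surveys of
5,000 over 20 binary outcomes for the OR battery; 2 × 250 people over a
4-question battery with latent-offset correlation for the GEE test,
rejection bands 0.05 ± 0.02); bias-detection and bootstrap-validity checks
use 200 replicates at n = 2,000 per survey with a joining log-OR of 0.8 on
a covariate carrying a log-OR of 1.0 into half the outcomes (an OR of
~2.7 — a plainly "driving" effect); selector-recovery checks use 200
replicates at the study's combined sample size (4,459 + 2,000). The
end-to-end pipeline tests run a reduced replica (population 25,000, web
surveys of 600, B = 10); the default scenario (population 120,000,
probability survey 8,969, web surveys ~2,000, omnibus 9,176, B = 100)
reproduces the study shape and runs in a few minutes on one core.

## Design choices where the design was open

* Entry criterion for stepwise selection: LRT, not Wald.
* Relaxation policy: largest-shortfall release with grouping slack (above).
* "Two basic surveys combined": pooled samples, not per-outcome averaging;
  both are reported when they disagree appreciably.
* Aggregate-benchmark variance: fixed-benchmark delta method (no
  benchmark-side variance).
* Microdata regressions: robust (sandwich) rather than model-based
  variance.
* GEE mean model: both the per-question and common-effect readings are
  computed; the joint Wald test on the per-question model is primary.
* The stepwise membership model does not condition on the basic quota
  variables by default.
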