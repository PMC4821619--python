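# Methods

## Scope and model

`robmeta` implements the analytic pipeline of a RoB-stratified re-analysis of
published meta-analyses of non-randomized studies: ordinal domain-level
risk-of-bias judgments aggregated to overall study ratings, generic
inverse-variance random-effects pooling of study-level relative risks, and
sensitivity re-analysis after excluding studies above a maximum acceptable
overall RoB, with two-rater weighted-kappa agreement for the judgments
themselves.

All effect measures (OR, HR, RR, IRR, relative rate) are treated
interchangeably on the natural-log scale, as the source reviews did; the
measure label is retained for reporting only. Estimates are stored exactly as
printed (two decimals) and never re-derived from participant counts, so the
printed tables are the single source of truth.

## Risk-of-bias aggregation

A study profile holds seven ordinal judgments (low=0 < moderate=1 <
serious=2 < critical=3), in chronological domain order: confounding and
participant selection (pre-intervention), intervention measurement (at
intervention), departures from intended intervention, missing data, outcome
measurement, and selective reporting (post-intervention).

The base overall rule is the maximum domain level: all-low gives low; any
critical gives critical; otherwise the highest level present. Reviewer
discretion to treat concerns in multiple domains as additive is formalized as
a counting rule (`EscalationPolicy`): if the base overall is moderate and at
least `moderate_to_serious_threshold` domains sit at exactly moderate, the
overall becomes serious; analogously serious → critical. Escalation is
applied once per aggregation — a moderate base can never cascade to critical
— because no study in the reference tables exhibits a cascade and the
single-step rule is the simplest consistent formalization.

Both thresholds default to 3. This value is the empirical choice that exactly
reproduces all 37 published consensus overall ratings in the packaged
fixtures: studies with two moderate domains (e.g. Fischer 2005,
Hippisley-Cox 2005) stay moderate, studies with three or four (Brownstein
2010, Curtis 2003, both Kimmel studies, Solomon 2002) become serious, and the
one study with three serious domains (Pantalone 2009) becomes critical. A
single domain never escalates, so thresholds below 2 are rejected. The
concordance of the threshold-3 rule with all 37 consensus ratings is asserted
by an explicit test; it is a sufficient formalization of the published
judgments, not necessarily the process the original reviewers followed.

Guaranteed properties (property-tested): raising any single domain judgment
never lowers the overall; with escalation disabled the overall equals the
maximum domain level; with escalation enabled the result is at least the
disabled result and exceeds it by at most one level.

## Effect pooling

Study effects enter as y_i = ln RR_i with standard errors back-calculated
from the printed confidence limits:

    se_i = (ln U_i − ln L_i) / (2 z),  z = Φ⁻¹(1 − (1 − ci_level)/2)

(z = 1.959964 at the 95% default; the quantile comes from scipy, so other CI
levels are supported). A zero-width CI is rejected rather than silently
producing se = 0.

Fixed-effect weights are w_i = 1/se_i²; Cochran's heterogeneity statistic is
Q = Σ w_i (y_i − mu_FE)². The between-study variance uses the
DerSimonian–Laird moment estimator, truncated at zero:

    tau² = max(0, (Q − (k−1)) / (Σw_i − Σw_i²/Σw_i))

Random-effects weights are w*_i = 1/(se_i² + tau²); the pooled log effect is
the w*-weighted mean with SE (Σw*_i)^(−1/2), and CIs are z-based
(exponentiated on output). DerSimonian–Laird with z-based intervals was
chosen deliberately — it is the convention of the standard review software
whose output the fixtures reproduce — and REML, Paule–Mandel and
Hartung–Knapp variants are intentionally not offered. Q, tau² and I² =
100·max(0, (Q − df)/Q) always derive from the fixed-effect weights, the
standard definition, whichever model produced the estimate. With k = 1 the
pooled result equals the single study's (tau² = 0, I² = 0, with a
degenerate-input warning from the tau² estimator); identical inputs give
Q = 0 and I² is defined as 0 there.

Design-stratified synthesis (`pool_by_subgroup`) pools each design stratum
with its own tau² and the overall column as one synthesis of all studies with
a single tau² — not a combination of the subgroup results — which is why the
overall CI can be narrower than either stratum's. Empty strata are omitted
rather than reported as zero-study pools.

Numerical conventions: weights are reported normalized to sum to 1;
display rounding is two decimals for ratio estimates and whole percent for
I², matching the precision of the source tables; full precision is retained
on every result object and in JSON export.

## Sensitivity analysis

`Scenario.analysis_A()` retains studies with overall RoB ≤ moderate;
`Scenario.analysis_B()` retains only low. Filtering requires every study in
the effect set to be classified (an unclassified study is an error naming
it, not a silent drop) and preserves input order. Reports carry the paired
subgroup syntheses, the excluded (study, level) list, the full-precision
log-scale delta, a `no_change` flag (true when estimate and both CI bounds
are identical at two-decimal display precision, mirroring how the source
tables mark unchanged cells), and a significance transition (gained / lost /
unchanged) defined solely by whether the 95% CI excludes 1. If filtering
empties the set, the post-analysis is marked not estimable rather than
raising.

## Agreement

Linearly weighted Cohen's kappa for two raters: with contingency proportions
p_ij over k ordered categories and weights w_ij = 1 − |i−j|/(k−1),

    kappa = (Σ w_ij p_ij − Σ w_ij r_i c_j) / (1 − Σ w_ij r_i c_j)

where r and c are the row and column marginals. The category set is declared
a priori (default: the four RoB levels) and zero rows/columns are retained;
since per-domain judgments often use fewer than four observed levels and the
convention changes the expected agreement, it is an explicit, documented
choice rather than inferred from the data. Both raters constant on a single
category makes the expected agreement 1 and kappa undefined — this raises a
distinct error rather than returning 1. No CI is attached by default; an
optional seeded nonparametric bootstrap (resampling units) provides a
percentile interval. The published per-domain kappa values for the two
reviews cannot be recomputed here because the raters' pre-consensus
judgments were never published; the statistic is therefore validated against
closed forms, a brute-force direct-summation oracle, and statsmodels'
implementation on randomized instances instead.

## Synthetic data

`simulate_effect_set` draws, per study: an overall RoB level from a
configurable distribution (default matching the 8/18/9/2 low/moderate/
serious/critical mix of the 37 fixture studies); a study-specific true log
effect theta_i ~ Normal(mu + bias[level], tau²); a standard error se_i
uniform on 0.05–0.35 (spanning the SEs back-calculated from the fixture
tables); and an observed y_i ~ Normal(theta_i, se_i²), stored as
exp(y_i) with CI exp(y_i ± z·se_i). The bias mechanism is an additive
log-scale shift per RoB level — the simplest structure under which excluding
high-RoB studies should move the pooled estimate toward the truth, which is
exactly what the recovery test checks. Cohort/case–control labels are
Bernoulli(design_prob = 0.5, roughly the published mix).

`simulate_rating_pairs` draws both ratings from a shared marginal and forces
agreement with probability `agreement_boost` (0 = independence null,
1 = perfect agreement). `simulate_rob_profiles` draws the seven domains
independently from per-domain level distributions.

All generators take an explicit integer seed and use one local
`numpy.random.default_rng` per call; no global state.

What the generators do *not* emulate: correlated effects within a study
(the same cohort contributing several outcomes or drugs), correlated domain
judgments within a study, non-normal effect distributions, small-sample
biases in the published estimates, and publication selection. Passing the
recovery and coverage tests therefore shows the estimators are correct under
the assumed random-effects model, not that real review data satisfy that
model.

## Problem sizes and checks

The published-data checks run on the fixture tables themselves (15-, 9-,
7-study syntheses and their stratified re-analyses) and complete in
milliseconds. The stochastic checks use 500 replicates at k = 200 studies
for unbiasedness of the pooled log effect (within 3 Monte-Carlo SEs),
relative bias of the tau² estimate (≤ 15% at tau² = 0.05), and 95% CI
coverage (93–97% at tau² = 0); moment checks of the generator use a single
k = 5000 draw; the bias-recovery property uses 200 replicates at k = 30.
These sizes give stable verdicts at negligible cost.

## Known limitations and open discrepancies

- Comparisons against printed pooled values use ±0.01 on ratio estimates and
  CI bounds and ±3 percentage points on I², since the inputs are themselves
  rounded to two decimals and that rounding propagates.
- Two printed values in the reference tables are not reproducible from the
  printed inputs under any pooling variant tried (DL, fixed-effect,
  subgroup-specific tau², leave-one-out), with the computation confirmed
  against independent implementations: the all-study ibuprofen CI lower
  bound (printed 0.97; computed 0.952, with estimate and upper bound
  agreeing) and the heart-failure low-RoB-only I² (printed 16%; computed
  39%, where the accompanying printed CI matches a fixed-effect pool of
  those four studies). The corresponding test assertions are kept at face
  value and fail, documenting the discrepancy rather than hiding it.
- The heart-failure and mortality row counts printed in the source summary
  table (8 and 8) disagree with the study table itself, which prints 9 and 7
  estimates (its own text confirms 31 estimates in total); the fixtures
  follow the study table.
- One study in the COX-2 review published no per-drug estimates; it appears
  in the RoB fixture (21 profiles) but contributes no effect rows, and the
  "any/other NSAID" exposure group, for which no per-study data were
  printed, is not representable.
- No funnel plots, publication-bias tests, meta-regression,
  continuous-outcome synthesis, leave-one-out influence diagnostics, or
  GRADE-style certainty grading; the seven-domain instrument is fixed, with
  no extensibility to other RoB instruments.
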