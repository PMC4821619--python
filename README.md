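# robmeta

Risk-of-bias-stratified meta-analysis of non-randomized studies of
interventions.

Systematic reviews of drug safety frequently pool non-randomized
(pharmacoepidemiological) studies, which are exposed to confounding and a
range of other biases that randomization would have controlled. `robmeta` is
for epidemiologists and review methodologists who want to (a) turn
domain-level risk-of-bias (RoB) judgments into overall study ratings with an
explicit, reproducible rule, (b) pool published relative risks with
inverse-variance random-effects synthesis, and (c) ask whether restricting
the analysis to lower-RoB studies materially changes the pooled estimate —
all from the study-level numbers as printed in review tables.

The package ships the component-study tables of two widely cited safety
reviews as fixtures: 16 studies of rosiglitazone vs pioglitazone
(myocardial infarction, heart failure, mortality) and 21 studies of COX-2
inhibitors and nonselective NSAIDs vs non-use (eight drug exposure groups),
together with the consensus seven-domain RoB judgments for all 37 studies.

## Methods at a glance

**Risk-of-bias aggregation.** Each study carries seven ordinal domain
judgments (low < moderate < serious < critical) for confounding, participant
selection, intervention measurement, departures from intended intervention,
missing data, outcome measurement, and selective reporting. The overall
rating is the maximum domain level, with reviewer discretion for additive
concerns formalized as an escalation rule: ≥ 3 domains at moderate escalate a
moderate overall to serious, and ≥ 3 at serious escalate a serious overall to
critical (both thresholds configurable). With the defaults the derived
overall matches the published consensus rating for all 37 fixture studies.

**Pooling.** Study effects enter on the log scale, y_i = ln RR_i, with
standard errors back-calculated from the printed 95% limits,
se_i = (ln U_i − ln L_i)/(2·1.959964). The random-effects pooled estimate is

    mu_hat = Σ w*_i y_i / Σ w*_i,   w*_i = 1/(se_i² + tau²),

with the DerSimonian–Laird moment estimator
tau² = max(0, (Q − (k−1)) / (Σw_i − Σw_i²/Σw_i)) computed from the
fixed-effect weights w_i = 1/se_i², Q = Σ w_i (y_i − mu_FE)², and
heterogeneity summarized as I² = 100·max(0, (Q − df)/Q). Confidence
intervals are z-based. Cohort and case–control strata are pooled separately
and jointly.

**Sensitivity analysis.** Scenario A excludes studies with serious or
critical overall RoB; scenario B retains only low-RoB studies. Reports pair
the original and re-pooled results with exclusion lists, full-precision
deltas, and whether statistical significance (95% CI excluding 1) was gained
or lost.

**Agreement.** Two-rater agreement on the ordinal judgments is measured by
Cohen's kappa with linear weights w_ij = 1 − |i−j|/(k−1), over the full
declared category set, with an optional seeded bootstrap CI.

## Worked example

```python
import robmeta as rm

tzd = rm.load_fixture("tzd_effects")
mi = tzd.select(outcome="myocardial_infarction")
print(rm.MetaAnalysis(mi).fit().summary())
```

```
Meta-analysis: tzd/myocardial_infarction
  model: random effects (DerSimonian-Laird), generic inverse variance, log scale
  studies: 15
  pooled estimate: 1.16 (1.07-1.24)  [log 0.1452 (SE 0.0374)]
  heterogeneity: Q = 25.81 (df = 14), tau2 = 0.0079, I2 = 46%
          cohort: k = 11  1.16 (1.05-1.28)  I2 = 59%
    case_control: k =  4  1.15 (1.04-1.27)  I2 = 0%
```

Across all 15 studies, rosiglitazone is associated with a 16% higher odds of
myocardial infarction than pioglitazone, with moderate between-study
heterogeneity. Restricting to the six studies rated low RoB:

```python
cls = rm.classify_studies(rm.load_fixture("tzd_rob"))
rep = rm.run_sensitivity(mi, cls, rm.Scenario.analysis_B())
print(f"retained {rep.n_post}/{rep.n_original}; "
      f"{rep.original.overall.display()} -> {rep.post.overall.display()}; "
      f"significance {rep.significance_change}")
```

```
retained 6/15; 1.16 (1.07-1.24) -> 1.06 (0.99-1.13); significance lost
```

The elevated risk is no longer statistically significant once only the
low-RoB studies are pooled — the substantive point of RoB-stratified
re-analysis.

The same operations are available from the shell:

```bash
robmeta pool --effects effects.csv --outcome myocardial_infarction --by design --forest
robmeta rate --rob rob.csv
robmeta sensitivity --effects effects.csv --rob rob.csv --scenario both
robmeta kappa --ratings ratings.csv
robmeta simulate effects --config cfg.json --out sim.csv
```

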