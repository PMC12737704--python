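# Methods

## Setting and conventions

The package operates on cohorts of single-timepoint assessments: a summated
Likert total score on the integer grid `[n_items·item_min, n_items·item_max]`
(default 13 items scored 1–5, totals 13–65) and a binary reference outcome
coded 1 for the event being screened for. A respondent is classified
screen-positive when `score ≥ c`; sensitivity is always the detection rate of
outcome 1. Candidate cut-offs default to `score_min … score_max + 1`, so both
degenerate ROC corners (everyone positive / nobody positive) are reachable.

Missing data are handled by listwise deletion with an explicit exclusion log
(retained + excluded = input rows, per cohort); no imputation is offered.

## Discrimination

The AUC is the tie-corrected pairwise concordance: over all
(positive, negative) pairs, credit 1 when the positive scores higher, 0.5 on
a tie, averaged. On a coarse integer grid ties are frequent, and this
statistic equals the trapezoidal area under the empirical ROC polyline
including its degenerate endpoints; it is computed in `O(n log n)` via
midranks.

Confidence intervals come from a bootstrap **stratified by outcome**:
resampling with replacement within each outcome class, preserving class
sizes, so no resample can lose a class (which would leave the AUC
undefined). When assessments are clustered within participants, the
resampling unit is optionally the participant cluster, stratified by the
cluster's outcome (a cluster containing any case resamples in the case
stratum). Two intervals are available:

* *percentile* — the (α/2, 1−α/2) empirical quantiles of the bootstrap AUC
  distribution, using the inclusive linear-interpolation quantile
  convention so results are bit-reproducible under a fixed seed;
* *BCa* — percentile end-points adjusted for median bias
  `z0 = Φ⁻¹(#{AUC* < AUC}/B)` and for skewness through the jackknife
  acceleration `a = Σ(θ̄−θᵢ)³ / (6[Σ(θ̄−θᵢ)²]^{3/2})` (delete-one record, or
  delete-one cluster when clustered; delete-one AUCs are computed in
  `O(n log n)` from per-record concordance totals). If every bootstrap value
  falls on one side of the estimate (z0 infinite — typically a degenerate
  AUC of exactly 1), the interval falls back to percentile and the result is
  flagged.

Default `B = 10,000` resamples at level 0.95. Predictive values are always
computed from (Se, Sp, prevalence) by Bayes' rule rather than from raw
counts, making prevalence an explicit, swappable argument; at the cohort's
observed prevalence the two routes coincide exactly, which the tests assert.

## Cut-off derivation

On the derivation cohort, Youden's `J_c = Se_c + Sp_c − 1` is profiled over
the candidate grid. Ties at the maximum resolve to the **lower** cut-off: a
lower threshold flags more respondents and preserves sensitivity, the right
bias for a screening rule.

* **Plateau**: `P = {c : J_c ≥ J_max − ε}` with ε = 0.01 — cut-offs whose
  discrimination is practically indistinguishable from the optimum. P need
  not be contiguous; contiguity is reported, not enforced.
* **Admissibility**: `c ∈ P` is admissible when `Sp_k(c) ≥ τ` in a *strict*
  majority of the K cohorts (τ = 0.75; the majority threshold 1/2 is
  configurable, e.g. for even K). The derivation cohort counts as one of the
  K. The per-(cut-off, cohort) pass table is part of the decision trail. An
  empty admissible set is a legitimate, explicitly signalled outcome — the
  error object carries the plateau and floor table rather than silently
  falling back.
* **Selection**: `c* = min(A)`, again favouring sensitivity.

The **Index of Union** provides a second, prevalence-agnostic criterion:
`IU_k(c) = |Se_k(c) − A_k| + |Sp_k(c) − A_k|` scores how far both margins sit
from the cohort's own separability target (its AUC); ties break by smaller
`|Se − Sp|`, then lower c. The aggregate `IU_agg(c) = Σ_k w_k·IU_k(c)` uses
unnormalised equal weights `w_k = 1` — a sum, not a mean — and its argmin
(same tie cascade, applied to the weighted margins) is compared with `c*`.
The IU machinery also accepts published summary tables (Se/Sp per cut-off
plus AUC per cohort) in place of raw data.

## Test–retest reliability

For n subjects × k = 2 administrations, the two-way crossed ANOVA (one
observation per cell) gives `MS_R` (subjects), `MS_C` (administrations) and
`MS_E` (residual). Absolute-agreement intraclass correlations:

```
ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E))
ICC(A,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n)
```

Absolute agreement charges any systematic mean shift between administrations
as disagreement — the conservative choice when asking whether a later
administration can replace an earlier one — and the tests assert the strict
decrease under a pure timepoint-2 shift (which a consistency ICC ignores).
Confidence intervals use the F-distribution construction for
absolute-agreement ICCs with a Satterthwaite-style denominator df for the
compound variance `a·MS_C + b·MS_E`; average-measure bounds are the
single-measure bounds pushed through the Spearman–Brown step-up. Point
estimates and intervals are verified against an independent reference
implementation in the test suite. Negative estimates are reported as-is
(band "poor"), never truncated.

Measurement precision: `SEM = SD_t1·√(1 − ICC(A,1))` anchored on the
first-administration SD (a pooled-SD anchor would also be defensible; the
first administration is the natural baseline for prospective change
detection), `SDC_individual = 1.96·√2·SEM`, `SDC_group = SDC_individual/√n`.
Internally the chain keeps full precision; reported tables round
half-away-from-zero at presentation only. (When reproducing published
chains that started from a rounded SEM, `sdc_from_sem` applies the chain to
the reported value.)

Interpretation bands for ICC point estimates: < 0.50 poor, 0.50–0.75
moderate, 0.75–0.90 good, > 0.90 excellent.

## Synthetic study generator

`generate_cohort` draws class-conditional normal ("binormal") latent scores,
rounds to the integer grid and clips to the scale range. Class sizes are
fixed at `round(n·prevalence)` — not binomial — so prevalence is exact and
bootstrap strata are never empty. Closed forms give free oracles: the latent
AUC `Φ((μ₊−μ₋)/√(σ₋²+σ₊²))`; the exact AUC of the discretised scores; exact
population operating points `Se(c) = 1 − F₊(c−0.5)`, `Sp(c) = F₋(c−0.5)`
(the half-integer shift matches "rounded score ≥ c"); and hence the exact
population-optimal integer cut-off.

The default `five-cohort` preset emulates a two-country, five-dataset
validation design: n = (504, 462, 491, 500, 500), outcome prevalences
(0.092, 0.092, 0.084, 0.181, 0.202), latent AUC targets
(0.96, 0.97, 0.89, 0.85, 0.76). Class SDs are 6 score points (the implied
observed total-score SD is ≈ 8, typical for such scales). Each cohort's
negative-class mean is anchored so the population specificity of "≥ 35"
equals the corresponding cohort's published operating value
(0.874/0.870/0.772/0.819/0.628); the positive-class mean then sits at the
distance producing the AUC target. This reproduces the reference study's
case-mix heterogeneity: the specificity floor holds in a majority of
cohorts from ≈ 34 upward, and per-cohort population-optimal cut-offs
scatter over 34–36. The second cohort reuses a subset of the derivation
cohort's participant ids so cluster-aware resampling has real clusters to
work with. The paired retest cohort uses a latent-trait model (trait
`N(33, 7.49)`; the trait SD is chosen so the observed first-administration
SD is ≈ 7.97 at true ICC 0.884) with administration noise set from the
target absolute-agreement ICC, plus an optional timepoint-2 mean shift.

What the generator does **not** emulate: item-level responses and factor
structure (totals and subscale scores only), non-normal or skewed score
distributions, cohort-specific score–outcome dependence beyond a location
shift, and attrition mechanisms. Passing tests therefore certify the
algorithms and their sampling behaviour under a clean binormal world, not
the psychometrics of any real instrument.

## Plateau identifiability at realistic sample sizes

A structural limitation worth stating plainly: with ≈ 500 respondents at
≈ 9% outcome prevalence, the derivation cohort has ≈ 46 cases, so the
empirical J profile moves in sensitivity quanta of 1/46 ≈ 0.022 — larger
than the plateau half-width ε = 0.01. The empirical maximum therefore
typically exceeds J at the population-optimal cut-off by more than ε, and
the empirical ε-plateau is usually only one or two integers wide. Two
consequences: (i) the plateau observed on any single cohort of this size is
a noisy estimate of the population plateau, and a Monte-Carlo check of
"population optimum ∈ empirical plateau" fails far more often than a naive
reading of ε would suggest (the acceptance script reports this recovery
rate honestly); (ii) rarely (≈ 2% of preset seeds) the empirical plateau
lands entirely below the floor-admissible region and the derivation
correctly reports "no admissible cut-off". Aggregating across cohorts —
the specificity floor and IU_agg — is precisely what stabilises the final
selection: the modal derived cut-off across replicate studies concentrates
on a single value even though single-cohort optima wander.

## Numerical and interface choices

* Half-away-from-zero rounding to 3 decimals in presentation tables only.
* One seeded `numpy` generator per stochastic run; study-suite and
  acceptance seeds are spawned from a single root seed.
* `LR+ = ∞` at Sp = 1 and `LR− = ∞` at Sp = 0 are flagged values, not
  exceptions.
* Plotting never recomputes metrics: figures are drawn from the same tidy
  tables the metrics layer produced, and those tables — not pixels — are
  the tested surface.
* CLI exit codes: 0 success, 1 validation/usage error, 2 well-posed but
  impossible computation (single-class cohort, empty admissible set).
  Flags override config-file values, which override built-in defaults.

## Known limitations

* Two administrations only (k = 2) for reliability; no Bland–Altman
  analysis, no consistency-type ICCs.
* No smoothed/parametric ROC, partial AUC, or correlated-AUC comparison.
* One operational cut-off per run by design; cost-weighted or
  prevalence-weighted utility cut-offs are out of scope.
* Which items form each subscale, and any reverse-keying, must be supplied
  in configuration — the package hard-codes no item assignments.
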