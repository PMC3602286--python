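# Methods

## The problem

The CES-D asks for the frequency of 20 feelings over the previous week on a
0–3 scale; 16 items are negatively worded, four positively worded and
reverse-scored, the total is 0–60, and a total ≥ 16 indicates high
depressive symptoms (hDS). When subjects skip items, the analyst must choose
between complete-case analysis, deterministic single imputation, multiple
imputation under an ignorability assumption, or an explicit sensitivity
analysis against nonignorable missingness. This package implements that
entire decision space so the choices can be compared quantitatively.

All data structures are pandas DataFrames with item columns
`item_01..item_20` (NaN = missing) on the *scored* scale; `reverse_code` is
an explicit ingestion step, so downstream code never branches on item
polarity except where MNAR scenarios distinguish negative from positive
items. The positive items default to positions {4, 8, 12, 16}, the
instrument's canonical placement, and are configurable.

## Bound-based classification

A partially observed subject is classified without imputation when every
completion of the missing items agrees: hDS if the observed sum already
reaches the cut-off, NhDS if observed sum + 3·(number missing) stays below
it, undetermined otherwise. Counting every undetermined subject as non-case
or as case yields the minimum- and maximum-imputation prevalence bounds.
Reported percentages are rounded half-up to one decimal.

## Chained-equations engine

Missing cells of each target are initialised by uniform draws from that
variable's observed values; targets are then revisited for `n_iter` cycles
in order of increasing missing count, each re-imputed from the current
completions of its predictors. The m imputations run on independent
child streams spawned from the master seed, so a fixed seed reproduces the
full output bit-for-bit and observed cells are never modified.

Elementary methods:

- **pmm** — Bayesian linear regression with the standard draw
  (σ*² = RSS/χ²_ν, β* ~ N(β̂, σ*²(XᵀX + λD)⁻¹)); each missing case copies
  the observed value of one of the `donor_k = 5` donors whose unperturbed
  predictions are nearest to the case's perturbed prediction, ties broken
  uniformly at random (implemented as sub-10⁻⁹ jitter on distances).
  Imputations therefore stay inside the observed support and need no
  clipping.
- **polyreg / logreg** — multinomial or binary logistic regression with a
  small ridge penalty (λ = 1e-4 per observation); parameter uncertainty
  enters by refitting on a bootstrap resample of the observed rows each
  imputation. A bootstrap refit was chosen over a normal approximation to
  the multinomial coefficient covariance because the covariance is
  expensive and fragile under sparse categories, while the bootstrap is a
  standard proper-imputation device with the same large-sample behaviour.
  Every level of the declared support receives a floor probability
  (10⁻¹²), so categories absent from the observed rows are never strictly
  impossible. Categories are sampled by inverse-CDF against a single
  uniform draw per cell, which is what makes common-random-number
  comparisons across scenarios meaningful.

Collinearity and n < p designs are handled by the always-on ridge (escalated
with a logged warning when the penalised normal equations are still
singular) rather than by dropping columns, which keeps behaviour continuous
in the data.

Model structures: `score_pmm` (total score from the 17 covariates),
`status_logreg` (binary hDS flag from the covariates), `items_parsimonious`
(each item from the other 19) and `items_full` (items plus covariates). For
the score/status paths the derived variable is treated as observed only for
subjects with zero missing items; partially determined subjects are instead
served by the bound-based classifiable-case analysis, since mixing the two
observability notions would make the imputation model's "observed" set
depend on the classification rule.

Defaults: m = 5 imputations, `n_iter` = 10 cycles, `donor_k` = 5. The
multi-run studies (amputation benchmark, sensitivity scans, test suite) use
`n_iter` = 5: item-level chains on this data are memoryless enough that
traces stabilise within 2–3 cycles, and halving the cycles doubles the
replication the studies can afford.

### Rubin pooling

Point estimate = mean of the m estimates; total variance
T = W̄ + (1 + 1/m)B with W̄ the mean within-imputation variance and B the
between-imputation sample variance. Pooled prevalence uses per-dataset
binomial variances p̂(1−p̂)/n. The reported SD after MI is the mean of the
per-dataset SDs (a descriptive convention; only the SEM carries the
between-imputation penalty).

## Nonignorable sensitivity analysis

Pattern-mixture tilting in three steps: fit the ignorable model, tilt its
predictive distribution for nonresponders, re-impute. For categorical
targets the tilt is p′_c ∝ p_c·θ_c (θ₀ ≡ 1) applied at the sampling step of
*every* chained-equation cycle — the scenario modifies the imputation model
itself, not the finished imputations. For continuous targets the model
prediction is shifted by δ before donor matching, so imputations remain
observed-support members drawn from donors near the shifted prediction.

θ triplets are applied to the scored (post-reverse-coding) categories for
both item groups, encoding "nonresponders carry more symptoms" uniformly;
whether to tilt raw or scored categories for positive items is a genuine
ambiguity and this convention is the package's documented choice. Four
built-in scenarios run from (1.2, 1.5, 2.0) on all items to (4, 6, 10) on
negative and (6, 10, 15) on positive items — the positive items get larger
shifts because skipping them is plausibly more symptom-related. The
identity scenario (all θ = 1, δ = 0) is bit-identical to the ignorable run
under a shared seed; this is guaranteed by applying the (trivial) tilt and
renormalisation unconditionally so the two code paths perform identical
floating-point operations and RNG draws. The status-level path accepts a
single odds ratio but ships no defaults, there being no published anchor
values for it.

## Synthetic cohort

Items follow a graded-response-style mechanism: subject trait
t ~ N(0, 1), item propensity a_j·t + ε, ε ~ N(0, 1), categorised at three
per-item ordered thresholds. Defaults (loadings 0.60–0.98, thresholds from
per-item cumulative probabilities near (0.64, 0.86, 0.955)) were calibrated
once by simulation at n = 2·10⁵ against the published aggregate structure:
Cronbach α ≈ 0.89, hDS prevalence ≈ 25–26%, and a first correlation
eigenvalue ~7× the second. The generated mean score (~10.7) sits somewhat
below the published complete-case mean (11.89) and the SD (~9.4) somewhat
above (8.20); the calibration targets were α, prevalence and eigenvalue
dominance, and no attempt was made to match all four moments with one
latent factor.

The 17 covariates (age, marital status, employment, education, pregnancy
history, menopausal status, help needed with the questionnaire, depression
history, current treatment, psychotropic use, menopausal mood symptoms,
alcohol g/day, smoking, sleep duration, two hospitalisation flags, chronic
disease count) carry mild associations to the trait through latent-index
models; names mirror the classical depressive-symptom risk-factor list for
readability, but the distributions are inventions. They give the full and
score/status imputation models genuinely informative mixed-type predictors
(continuous, binary, ordinal, and nominal columns exercising the one-hot
design path).

Missingness is generated per cell with probability expit(α + offset):
offset 0 for MCAR, a standardised covariate index times `mar_strength` for
MAR, and log θ_c for the cell's own scored category under MNAR. The
intercept α is solved by bisection so the expected fraction of subjects
with ≥ 1 missing item hits the target (default 0.448, the rate implied by
the published cohort totals). The MNAR parameterisation makes θ_c exactly
the odds ratio of category c between missing and observed cells — the same
quantity the sensitivity tilt assumes — so "generate with θ*, recover with
scenario θ = θ*" is a well-posed oracle. What the generator does *not*
emulate: real item-content effects (every item is exchangeable up to its
loading), covariate marginals of any particular cohort, and
questionnaire-design causes of missingness (page layout, item wording);
passing tests certify the statistical machinery, not those human factors.

## Amputation benchmark

`run_accuracy_study` deletes exactly k items for round(fraction·n) subjects
(MCAR by construction — positions depend only on the seed), re-imputes by
person-mean and by item-level MI (pmm and polyreg), and reports mean,
variance, SEM and prevalence per (k, method) averaged over replicates, with
per-replicate detail attached for Monte-Carlo-error comparisons. One
amputation per (k, replicate) is shared across methods so method contrasts
are paired. Desk scale is n = 2,000 with 5–10 replicates, replication
standing in for cohort size. The benchmark reports the whole k-continuum;
no special behaviour is attached to any particular cut-off such as k = 4,
whose folklore status the benchmark lets the user judge.

"Monte-Carlo error" in the benchmark's recovery and method-agreement checks
means the spread of a single study pass — the replicate SD of the estimator
(combined in quadrature for differences between methods) — since the study
design being emulated is a single amputation pass and replication here only
serves to estimate that spread. At this resolution a small genuine method
contrast is visible: pmm imputes slightly higher prevalence than polyreg as
k grows (under one percentage point at k = 10 on the default cohort), both
bracketing the truth; the curves remain indistinguishable at single-study
noise scale.

Under MCAR, person-mean imputation is nearly unbiased for the *mean* score
(it rescales the observed sum), so its failure mode is variance inflation —
the subject-level rescaling stretches the score distribution increasingly
with k, dragging the SEM and threshold-exceedance prevalence with it. The
recovery tests therefore read "person-mean bias" on the variance indicator,
where the signal is monotone and unambiguous at desk scale.

## Numerical conventions and edge cases

- Sample variances use ddof = 1 throughout (α, PCA input, pooling).
- PCA eigenvalues are computed on the correlation matrix; a constant item
  column is an error, as is a zero-variance total in α.
- Person-mean values stay fractional (no re-rounding to the item grid);
  subjects with all 20 items missing are excluded from person-mean
  summaries (its 0–19 MV stratum) and raise if imputed directly.
- `classify_partial` on a complete row agrees exactly with
  `classify_hds(score_total(row))`.
- A variable that is 100% missing, m < 2, a predictor with missing cells
  but no imputation method, and non-increasing generator thresholds are
  all rejected with explicit errors.
- Seeds: every stochastic entry point takes one integer seed;
  per-imputation and per-replicate streams are spawned via
  `numpy.random.SeedSequence` keys, never by arithmetic on the user seed.

## Known limitations

- The bootstrap refit in polyreg/logreg slightly underpropagates parameter
  uncertainty relative to a full Bayesian draw when the observed sample is
  small.
- The sensitivity tilt matches the generating MNAR mechanism exactly only
  at the margin; conditioning on the other 19 items makes the
  correspondence approximate, which is visible as a small residual gap in
  the θ*-recovery experiments (well inside Monte-Carlo error at desk
  scale).
- Convergence diagnostics are limited to the per-iteration mean/SD trace;
  there is no R̂-style statistic, passive imputation, or multilevel
  support.
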