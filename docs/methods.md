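# Methods

## Scope

`frailty-audit` implements an auditing pipeline for deficit-accumulation
frailty indices: it constructs three classic indices from deficit-level
data, decomposes each into the part explained by its own input variables
plus a *bias* term introduced purely by data manipulation, interprets
indices and statuses by forward-stepwise approximation, compares index
representations head-to-head as mortality predictors in a discrete-time
hazard model, and exhaustively scores equal-weight k-item alternative
indices. Because the cohort data this methodology targets (large panel
surveys of older adults with linked mortality) are registration-restricted,
the package ships a synthetic cohort generator that reproduces the
statistical structure the analysis relies on; every stage is exercised
end-to-end on generated data.

## The three frailty models

| model | construction | index range | frail iff | age rule |
|---|---|---|---|---|
| Functional Domains (FD) | sum of 4 domain scores (physical, weight-loss/nutritive, cognitive, sensory) | [0, 4] | index >= 2 | 65+ |
| Burden | 24 items each scaled to [0, 1], summed, divided by the item count | [0, 1] | index >= 0.2 | 70+ |
| Biologic Syndrome (BS) | sum of 5 criteria (weight loss, exhaustion, low energy expenditure, slowness, weakness) | [0, 5] | index >= 3 | 65+ |

The weight-loss domain is shared by FD and BS, so eight distinct FD/BS
domain variables exist; the Burden cognition domain (performance score +
proxy assessment, censored at 1) brings the total to nine derived domains
and hence nine domain-level bias variables.

Construction primitives:

* **Ordinal rescaling** — rank r of K ordered categories maps to
  (r − 1)/(K − 1); five categories give {0, 0.25, 0.5, 0.75, 1}, a
  dichotomous item gives {0, 1}.
* **Right-censored sums** — binary indicators are summed and capped at 1
  (a participant with both fair/poor hearing and eyesight has raw sum 2,
  from which the censoring discards 1).
* **Stratified quantile flags** — a continuous measure is flagged in its
  extreme 20% tail within strata: activity by sex; walk time (8 ft times
  converted once to 15 ft equivalents by the factor 15/8, stored in
  seconds) by sex × height group (sex-specific median split); grip
  strength by sex × BMI quartile. The threshold is the smallest value at
  which the cumulative (optionally survey-weighted) fraction reaches the
  target quantile, and ties at the threshold are all flagged — a
  deterministic rule that reproduces the over-coverage one observes when
  unweighted percentiles are applied to weighted survey data. Unweighted
  thresholds are the replication default (matching the original practice
  being audited); weighted mode is available.
* **Dichotomization** — status = 1 iff index >= cutoff, cutoff inclusive.

`FrailtyIndexBuilder` is fit/transform shaped: `fit` learns the stratum
boundaries and tail thresholds from a cohort, `transform` derives all
scaled items, flags, domains, indices and statuses, so thresholds can be
learned on one sample and applied to another.

## Bias decomposition

For each domain d with theory-based input design X_d (its own raw inputs,
plus the stratifiers for quantile domains — sex coded as a female
indicator, BMI as the derived measure), the bias variable is the ordinary
least-squares residual

    bias_d = d − X_d β̂  (intercept included, pseudo-inverse on
                          rank-deficient designs)

Bias has mean zero and is orthogonal to X_d by construction. Because
every index is a fixed linear combination of its domains (or scaled
items), and each domain is exactly fit + bias, the index is an exact
linear function of its input design columns together with its bias
columns: regressing the index on inputs ∪ biases returns R² = 1 to
machine precision — the identity that anchors the decomposition. The
share 1 − R²(inputs only) is the fraction of index variance introduced
purely by censoring, categorization and thresholding. Linear fits are
used throughout, including for binary domains, because variance-explained
shares are the quantity of interest. Dichotomization bias
(status − index) is reported separately from the nine domain-level bias
variables.

A note on a fine point: the OLS residual of a censored sum min(h+e, 1) on
h and e is nonzero on *every* response pattern (with balanced cells the
residuals are ∓1/4), not only on the both-problems rows; only as the
co-occurrence probability becomes small do the residuals concentrate on
the both-problems cell with value ≈ −1. The tests assert exactly this.

## Interpretation

Continuous indices are approximated with forward-stepwise linear
regression, statuses with forward-stepwise logistic regression. At each
step the candidate (or dummy block) minimizing AIC = 2k − 2·loglik is
added; selection stops when no candidate lowers AIC. Ties are broken by
candidate name order, so the path is deterministic and invariant to
column order. Fit statistics are refit from scratch at each cumulative
set; for logistic fits the pseudo-R² is McFadden's (1 − llf/llnull), with
a parameter-adjusted variant recorded alongside — the literature being
audited does not state which pseudo-R² it used, so the choice is declared
rather than guessed. Candidates that trigger perfect separation are
skipped and logged, never fatal. `variables_to_reach(path, f)` reports
the smallest number of selected variables reaching a fraction f of the
maximum R² attained — the "can a 24-item scale be simplified?" question.

AUC is the rank statistic (ties count one half), with a DeLong-type 95%
confidence interval from the structural components of the positives and
negatives, clipped to [0, 1]. It is cross-checked in the tests against
brute-force pairwise comparison and the Mann-Whitney U statistic.

## Discrete-time survival

Follow-up is yearly, at most 13 years. The person-period expansion gives
one row per participant per year at risk; a participant followed f years
contributes f rows with the event on the last row iff they died (a death
within year t is credited to period t). The hazard model is logistic
regression of the event on one dummy per period (no smooth baseline, no
separate intercept) plus predictors plus adjustment covariates (sex,
race/ethnicity dummies, education, per-capita income and wealth). Rows
with missing covariates are dropped with a logged count. With period
dummies only, the fitted hazards reproduce the Kaplan-Meier product-limit
estimate exactly (asserted to 1e-8), which pins the parameterization.
Wald p-values are reported for predictor significance. Proportional-
hazards (Cox) modelling is out of scope by design.

`compare_representations` fits the same covariate-adjusted model once per
representation — continuous index, dichotomous status, domain variables,
bias variables, raw inputs, and the equal-weight sum of the inputs — and
reports in-sample AUC with DeLong CI, AIC and residual deviance. The
equal-weight sum is a constrained point in the inputs' span, so the
inputs representation can never have higher residual deviance: that exact
nesting is asserted on every run. The constructed index itself is *not*
in the inputs' span (it also contains bias), so its comparison with the
inputs is an empirical question, answered in replicate tests.

## Alternative-index mining

An alternative index is the equal-weight sum of k >= 2 distinct pool
variables on their [0, 1] scale (so equal weights are comparable across
binary, ordinal and continuous items). The default menu has 72 variables
— 44 raw inputs, 19 derived intermediates, 9 domains — giving C(72, 4) =
1,028,790 four-item candidates. Each candidate's index enters the
covariate-adjusted hazard model; the Wald p of the index term, model AIC
and residual deviance are recorded, and the summary counts candidates
significant at 0.05, candidates with lower p than a reference frailty
index, and candidates with lower residual deviance. Non-convergent fits
are flagged, excluded from significance counts and reported separately.
No multiple-testing correction is applied — deliberately, since the point
is to expose how easily "significant" indices are found.

The per-candidate fits use a direct Newton-Raphson solver on a
precomputed design (one varying column), warm-started from the base
model; it maximizes the same likelihood as the statsmodels route and
agrees with it to ~1e-7 (asserted against fully independent statsmodels
refits of all 495 candidates of a 12-variable pool). The full 72-choose-4
sweep streams with checkpoints every 10,000 fits; the desk-scale default
uses pools of at most ~20 variables.

## Synthetic cohort generator

One latent frailty propensity Z — a standardized monotone function of age
plus standard-normal noise — drives all health variables:

* binary deficits: Bernoulli(logistic(a_j + b_j · λ · Z)) with
  per-variable baselines a_j and loadings b_j; λ (`frailty_loading`,
  default 1) scales every loading, and λ = 0 makes all deficits mutually
  independent;
* ordinal items: thresholded 0.8·λ·Z + noise at fixed standard-normal
  cutpoints;
* performance measures: walk time log-normal, increasing in Z with sex
  and height effects; grip strength normal, decreasing in Z with sex,
  height and BMI effects; activity log-normal decreasing in Z; cognition
  normal decreasing in Z;
* anthropometrics: sex-specific heights, BMI ~ N(27.5, 4.5) clipped;
* survey weights: i.i.d. Gamma with mean 1 and configurable dispersion —
  positive and right-skewed like design weights, with no claim to
  emulate any survey's weighting scheme;
* mortality: yearly death with probability logistic(α_t + β'x), default
  baseline log-odds rising from −3.3 by 0.07 per year (≈ 4–8%/yr) and
  default β = 0.9 on the latent factor; follow-up capped at 13 years.

The per-variable baselines were set so that default frailty prevalence
among the age-eligible lands in the realistic band for these instruments
(FD ≈ 0.36, Burden ≈ 0.47, BS ≈ 0.17 at defaults) and prevalence is
strictly increasing in λ. Missingness can be injected MCAR or with
probability increasing in age percentile (mean rate preserved);
demographics, weights and survival are never masked.

What the generator does **not** emulate: real marginal distributions or
item wordings, multi-wave longitudinal structure (a single baseline plus
survival suffices for this analysis), informative censoring, complex
survey design beyond a weight column, and any true multi-factor deficit
structure — a single latent factor is the simplest structure that makes
deficits correlated, age-graded and prognostic, which is all the
downstream stages assume. Passing tests therefore demonstrate
correctness of the *machinery* and the qualitative phenomena it measures
(bias shares, nesting, index-vs-status ordering, type-I calibration), not
numerical agreement with any real cohort.

## Missing-value handling

Two modes, mutually exclusive per run. The replication default imputes
by chained equations before constructing final indices: each incomplete
variable is regressed on all other analysis variables (linear for
continuous, logistic/multinomial for categorical), missing cells are
replaced by stochastic draws from the fitted conditional distribution,
and the cycle repeats (default 10 sweeps in the library, 5 in the
pipeline default) from a random-draw initialization; one completed
dataset is returned, deterministic given the seed. The
"missing-as-category" mode used for temporary indices treats a missing
item as contributing no deficit (lowest category; continuous values to
the median so they cannot land in an extreme tail) — the only
monotone-preserving reading of treating missingness as its own category
inside a sum.

## Numerical choices and degenerate inputs

* Quantile tie rule as above; an empty or all-missing stratum is an error.
* Rank-deficient bias designs are resolved by pseudo-inverse, never fatal.
* AIC tie-breaks by candidate name; stepwise stops on non-improvement.
* Logistic non-convergence and separation are flagged (fit retained where
  possible), and flagged mining fits never count as significant.
* A zero-variance index or a constant predictor is rejected with a clear
  error.
* All randomness flows from explicit integer seeds; same seed, same bytes.

## Problem sizes

The shipped tests run the statistical checks at the sizes the package
documents as its reference conditions: identity and independence checks
at n = 20,000 participants; parameter-recovery coverage over 40
replicates of ≈ 20,000 person-years; index-versus-status ordering over 50
replicates; miner type-I calibration as the average over 24 independent
zero-effect cohorts of the 495-candidate sweep (within one cohort the
candidates share variables, so a single sweep's significant fraction is
super-binomially dispersed; averaging independent cohorts restores the
nominal Monte-Carlo scale). The full 1,028,790-fit sweep is supported
but not exercised in the default suite.

## Known limitations

* Bias is defined linearly; nonlinear (tree/spline) decompositions are out
  of scope.
* Mined p-values are not corrected for multiplicity (by design, see above).
* The Burden item menu is a structural stand-in: the historical 38-measure
  mapping is not recoverable, so 24 generic items with a configurable
  divisor (24 or 30) are used.
* In-sample AUCs of multi-parameter hazard models carry the usual optimism
  (≈ params/events); the comparison table reports in-sample values, as the
  audited practice does.
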