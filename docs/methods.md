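# Methods

## Overview

`clpnet` estimates how dichotomous depressive symptoms predict one another
across the waves of a panel study. The core object is the cross-lagged
panel network (CLPN): for each pair of consecutive waves, every symptom at
wave *t+1* is regressed on **all** symptoms at wave *t* (plus binary
covariates), so each directed edge *j → k* is the log-odds coefficient of
symptom *j* at *t* in the model for symptom *k* at *t+1*, adjusted for the
other wave-*t* symptoms. Diagonal entries are autoregressive paths
(a symptom predicting itself); off-diagonal entries are cross-lagged
paths. Edges are also reported as odds ratios, where OR = 1 means no
association.

The package is organised as an analysis project: the numbered drivers in
`analysis/` tell the story (simulate → describe → missingness →
networks → Ising → bootstrap → comparison) and every computation lives in
`src/clpnet/` where the tests and the acceptance script import it.

## Node-wise estimation

Each node-wise regression is an L1-penalized (lasso) logistic model fit by
coordinate descent over a descending penalty path with warm starts, the
same objective as glmnet:

    (1/n) Σᵢ −ℓᵢ(b₀ + xᵢ'β) + λ‖β‖₁ ,

intercept unpenalized, predictors internally standardized and
coefficients reported back on the original 0/1 scale. The penalty is
tuned by stratified 10-fold cross-validated deviance. Folds come from a
seeded permutation stratified by outcome class so that rare symptoms
(endorsement down to ~12%) never produce an empty-class fold.

**Selection rule.** The default is the *one-standard-error* rule (largest
λ whose mean CV deviance is within one SE of the minimum); `"min"` is
available. The 1se default is a deliberate choice: in this design an edge
"exists" exactly when its lasso coefficient is nonzero, so the estimator's
false-discovery behaviour is part of the scientific contract. Under the
minimum-deviance rule the node-wise fits admit a large fraction of
spurious cross-lagged edges at realistic sample sizes, which would make
edge counts and replication percentages mostly noise; the 1se rule keeps
true-edge sign recovery intact while driving the false-positive rate
far below the 10% working bound used in the recovery experiments. The
trade-off is stronger shrinkage: see *Bootstrap accuracy* below.

**Numerical details.** The path uses 30 log-spaced penalties from just
above λ_max (where the null model is exact) down to λ_max·10⁻³;
convergence tolerance 10⁻⁷ on the coefficient scale for reported fits and
10⁻⁵ inside CV folds (fold fits only feed the deviance curve). At
penalty 0 the solver switches to a Newton–Raphson MLE. Constant predictor
columns receive an exact zero. A single-class outcome raises a
`DegenerateOutcomeError` rather than returning a degenerate model.

## Centrality

Cross-lagged in-expected-influence of item *k* is the sum of incoming
cross-lagged coefficients Σ_{j≠k} β[j,k]; out-expected-influence is the
row counterpart. Sums run on the **log-odds** scale — on the OR scale an
absent edge would contribute 1 per edge, contradicting "OR 1 means no
relationship". Autoregressive and covariate entries are excluded, matching
the *cross-lagged* in/out naming. z-scores standardize across the eight
items (divisor n). Items keep their raw response direction in networks
(the positively worded *happy* and *enjoyed life* are **not** reversed
there — their edges simply carry opposite sign); reversal applies only to
sum scores and internal-consistency coefficients.

## Cross-sectional Ising networks

Per wave, an eLasso-style Ising model: each item regressed on all others
with the same lasso machinery, penalty chosen per node by the extended BIC
with γ = 0.25, and the two directed estimates combined by the AND rule
(zero unless both nonzero, then their mean; OR rule optional). These are
pseudo-likelihood fits; no partition-function likelihood is attempted.
γ = 0.25 and AND are the established defaults of the eLasso approach; the
comparison of cross-sectional with temporal structure is reported as the
correlation between Ising weights and symmetrized cross-lagged weights —
a reporting convenience, not a formal test.

## Resampling

*Accuracy*: nonparametric bootstrap — subjects resampled with replacement,
the CLPN refit per replicate, percentile 2.5/97.5 intervals per edge. The
penalty is re-selected per replicate by default (reflecting the full
uncertainty of the procedure); fixed-penalty refits are available and much
faster. *Difference tests*: for each pair of edges (or items' expected
influences) the percentile interval of the bootstrap distribution of the
difference; significant iff it excludes 0; following the convention of the
bootstrap-network framework there is **no multiplicity correction** — read
the difference matrices as descriptive. *Stability*: case-drop bootstrap
at drop proportions 0.1–0.7; at each proportion the Spearman correlation
between subsample and full-sample centrality orders; the CS-coefficient is
the largest proportion at which ≥95% of subsamples correlate ≥0.7.
Spearman is the default (robust to the EI scale); Pearson by flag. A drop
proportion of 0 reuses the full-sample estimate, so its correlation is
identically 1.

**Bootstrap accuracy vs sparsity.** Percentile CIs for strong edges are
approximately calibrated only under the low-shrinkage `"min"` rule with
per-replicate re-selection; under the sparse 1se default the point
estimate itself is shrunk substantially toward zero and the interval
inherits that bias (measured in the test suite at scaled size). Edge CIs
should therefore be computed with `selection_rule="min"` when interval
coverage matters, and read as procedure-precision intervals otherwise.

## Missing data

*Little's MCAR test*: means and covariance estimated by EM under
multivariate normality (per-pattern conditional expectations), then
d² = Σⱼ nⱼ (ȳⱼ − μ̂ⱼ)' Σ̂ⱼ⁻¹ (ȳⱼ − μ̂ⱼ) over missingness patterns, χ²
with df = Σⱼ pⱼ − p. Applying it to binary items treats them as numeric —
standard applied practice, but a caveat worth remembering. Singular
pattern covariances fall back to a ridge-stabilized solve with a warning.

*Dropout model*: logistic regression of an ever-dropped-out indicator on
the covariates, baseline depression sum score and any extra columns;
complete separation falls back to a ridge-penalized fit, flagged.

*Imputation*: fully conditional specification. Missing cells initialize
from observed marginals; 20 sweeps (default; convergence monitorable via
the per-variable imputed-prevalence trace) revisit incomplete variables in
fixed column order. Each variable is regressed on all other item columns,
covariates and auxiliaries; coefficients are perturbed with a draw from
their asymptotic normal distribution (ridge 10⁻³ stabilizes sparse cells)
and missing entries redrawn as Bernoulli. One imputed dataset is retained
(network estimation is not compatible with multiple-imputation pooling);
`n_datasets` can emit several for sensitivity analyses. Observed values
are never altered.

Note an artifact visible in the example analysis: with ~70% of wave-9
subjects imputed from a model linking all variables, late-wave networks
pick up extra imputation-induced edges. That is a known cost of the
single-imputation strategy, not an estimator defect.

## Synthetic data generator

The motivating panel data are access-restricted, so the generator is the
test bed. It emulates: eight dichotomous items over nine waves with
wave-1 endorsement solved exactly to the published per-item rates
(covariate effects integrated out over the two binary covariates — gender
at 54%, ethnic-minority at 3%); a lag-1 logistic transition process whose
default matrix carries strong autoregression (strongest for loneliness
and restless sleep) and the recurrently reported cross-lagged paths among
the fatigue items, loneliness, mood items, and the two positively worded
items; and monotone MAR attrition with hazard
logistic(−2.0 − 0.05·gender + 0.40·ethnicity + 0.12·sum score), giving
roughly 13–14% per-wave dropout and ~68–70% cumulative dropout by wave 9.
With a nonzero transition matrix the transition intercepts subtract the
first-order drift term (B'·targets) so marginals stay near their targets;
the calibration is exact only at B = 0.

What it does **not** emulate: the source study is empirical and states no
generative model, so all of this is a stand-in. Wave-1 items are
independent given covariates — cross-sectional dependence only emerges
through the lag structure — so internal-consistency coefficients on
synthetic data are near zero rather than the ~0.9 of real symptom scales,
and wave-1 Ising networks are empty by construction. There are no
latent traits, no between-person stable differences (the very confound
the CLPN literature flags), no calendar-time effects and no intermittent
missingness by default. Passing tests therefore demonstrate estimator
correctness and pipeline behaviour under a known truth, not fidelity of
the substantive conclusions to real ageing-cohort data.

One global seed drives named RNG sub-streams (covariates, wave-1 draw,
transitions, attrition, bootstrap, case-drop, imputation), so every stage
is independently reproducible and bit-identical under a repeated seed.

## Comparison statistics

A cross-lagged edge replicates between two networks when it is nonzero
with the same sign in both. Because the natural denominator is ambiguous,
all three are computed: edges nonzero in the first network (default,
order-dependent), the union (order-invariant), and the order-invariant
mean of the two directed percentages ("either"). Edge-weight correlations
run over the fixed enumeration of all 56 off-diagonal positions on the
log-odds scale with zeros included — restricting to jointly nonzero edges
would conflate replication with correlation (a flag does exactly that for
sensitivity).

## Problem sizes in the validation suite

The validation experiments run at the sizes the estimator claims are
meaningful: moment reconstruction at the published wave Ns; recovery at
n = 10,000 with 100 replicates; MCAR calibration with 500 replicates at
n = 2,000; resampling contracts at n = 1,000 with B = 200; twin-sample
consistency at n = 10,000 per arm. Unit tests use smaller scaled designs
with assertions widened to the corresponding binomial/sampling envelopes;
each test's docstring states its design.

## Known limitations

- Between- and within-person variance are not disaggregated; edges mix
  both sources (inherent to CLPN on few waves).
- Difference tests are uncorrected for multiplicity by design of the
  framework they reproduce.
- Little's test applied to binary data relies on a normality
  approximation.
- Published-table moment reconstruction inherits the rounding of printed
  endorsement percentages (up to one unit in the last printed decimal).
- McDonald's omega, longitudinal measurement invariance, survey weights
  and graphical layouts are out of scope.
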