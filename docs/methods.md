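# Methods

## Model and procedure

The package estimates a prognostic risk score for right-censored overall
survival from bulk expression data. The covariates are not genes but ordered
gene pairs: pair k = (IRG1, IRG2) contributes the indicator
z_k(s) = 1{expr[IRG1, s] > expr[IRG2, s]}. A strict inequality is used and a
tie scores 0. Ties are measure-zero for continuous abundances but do occur
after rounding or in zero-inflated data, so the convention is fixed rather
than randomized. Pair orientation for *de novo* pairs is lexicographic in the
gene symbols; any fixed convention is equivalent for screening and fitting
because the model sees both directions through the 0/1 coding. A stored
signature is always scored with its own printed orientation.

The fitted risk model is a Cox proportional-hazards model with an L1 penalty
on the pair coefficients; the score IRGPI(s) = Σ_k z_k(s)·β_k is the linear
predictor over the selected pairs. Higher IRGPI means higher hazard.
Assumptions inherited from this model: proportional hazards of the pair
indicators, independent (non-informative) right-censoring, and samples that
are independent given the covariates.

## Stage-by-stage choices

**Gene variability filter.** Unscaled MAD (no 1.4826 consistency constant):
the 0.5 default threshold is only meaningful under a declared convention, and
the unscaled form is the simplest. The statistic is computed per cohort and a
gene must pass in every cohort supplied (the decision is an intersection, no
pooling). The threshold and the scaling are arguments, not constants. Whether
MAD is computed on the raw or log scale changes the kept-gene set (not the
pair values); the package computes it on the values as given.

**Pair filter.** A single frequency-window filter covers both "small
variation" and "imbalanced distribution": a pair whose frequency of 1 across
samples lies outside [low, high] = [0.2, 0.8] by default is dropped. The
20/80 window is the convention in the relative-ordering signature literature;
both bounds are configurable. The filter is idempotent and order-preserving.

**Screening.** Each pair is tested twice: a two-sample Mantel–Haenszel
log-rank test (p from a 1-df chi-square) and a univariate Cox fit with Efron
tie handling and Wald intervals. Selection defaults to the Cox p-value with a
flag to use the log-rank p instead; both are reported. Raw p-values are used
with no multiplicity correction — the screen is a pre-filter for a penalized
model that performs its own selection, and the null false-positive fraction
is checked empirically (it tracks α). Pairs with monotone likelihood
(perfect separation) or non-convergent fits are excluded rather than clipped.

**Penalized fit.** The lasso-Cox path is computed by glmnet-style coordinate
descent (scikit-survival's Coxnet). The penalty is chosen by k-fold (default
10) cross-validation on the Verweij–van Houwelingen partial-likelihood
deviance, D_k(λ) = −2·[l(β_(−k); all) − l(β_(−k); train_k)], with the log
partial likelihood evaluated under the Breslow convention. Folds are
stratified by event status and derived from a required seed, so the path,
the CV curve and the chosen λ are exactly reproducible. The default rule is
"min" (the CV-deviance minimizer); "1se" gives the sparsest model within one
standard error. Binary pair indicators share a scale by construction, so no
standardization is applied by default (a flag enables it). The reported
coefficients are the penalized estimates at the chosen λ — no unpenalized
refit — matching how the packaged signature's coefficients are defined.

**Cutoff selection.** The time-dependent ROC at horizon t is
cumulative/dynamic: cases are samples with an event by t, controls samples
under follow-up beyond t. Censoring before the horizon is handled by
inverse-probability-of-censoring weights from a Kaplan–Meier estimate of the
censoring distribution (cases weighted 1/G(T_i−), controls 1/G(t); Uno-type),
so early-censored samples inform the estimate through the weights rather
than being dropped. Candidate thresholds are the midpoints between
consecutive distinct scores plus ±∞ — exhaustive and deterministic, not a
grid. The chosen cutoff minimizes the Euclidean distance to (FPR 0, TPR 1);
distance ties resolve to the lower threshold (the larger high-risk group).
Risk assignment is strict: high iff score > cutoff, so a score exactly at
the cutoff is low risk. The default horizon is 1 year, converted into the
clinical table's declared unit (365.25 days or 12 months); time units are
metadata and never converted silently.

**Evaluation.** Kaplan–Meier curves and the log-rank test compare the risk
groups; time-dependent AUC reuses the IPCW estimator above; uni- and
multivariable Cox models (lifelines, Efron ties) combine the signature with
clinical covariates. The signature enters the multivariable model as the
binary group indicator by default, with a flag for the continuous score.
Stage is treated as ordinal numeric (I–IV → 1–4) by default, categorical on
request; other categorical covariates are one-hot encoded against a declared
(or lowest sorted) reference level. Exactly collinear covariates raise an
error naming the offending columns. P-values are reported exactly; display
floors like "< 0.001" are a presentation concern. The diagnostic
(non-survival) ROC uses midrank tie handling and accepts any score vector,
group label or continuous IRGPI alike.

## Synthetic cohorts

`synthetic_data.simulate_cohort` draws gene-wise log-normal expression
(log-mean 2.0; per-gene log-sd drawn uniformly from [0.3, 1.2] unless fixed),
computes the planted pair indicators by the same strict-inequality rule the
pipeline uses, and draws survival from an exponential baseline hazard
(default 0.02 events/month, median survival ≈ 35 months) multiplied by
exp(Σ β_k z_k) — the simplest proportional-hazards-consistent choice.
Censoring is independent exponential; its scale is root-found (bisection on
fixed uniform draws) so the realized censoring fraction hits the target
exactly, deterministically per seed. The default censoring target is 0.3:
long-follow-up cancer cohorts can censor far more heavily, but 30% keeps the
default cohort informative at the n = 300 scale the recovery experiments
use. Distortions are applied after survival generation, so outcome labels
depend only on the undistorted ranks: "monotone" applies an independent
strictly increasing map a·x^p + b (a, p > 0, b ≥ 0) per sample and is
provably invisible to the pair transform; "batch" adds a per-gene shift to a
random half of the samples and is the negative control showing the
invariance is per-sample monotone only.

What the generator does *not* emulate: count noise (negative binomial reads),
gene–gene correlation beyond the planted pairs, non-proportional hazards,
informative censoring, and cohort-level clinical covariates correlated with
expression. Passing tests therefore demonstrate correctness of the machinery
and calibration under the assumed model, not performance on real tumors.

## Problem sizes and numerical notes

The recovery experiments use 2 planted pairs (log-HR ±1.0) among 50 disjoint
noise pairs at n = 300 over 20 seeds; null calibration uses 200 noise pairs
at n = 300 for the screening false-positive rate and n = 1000 for the null
time-dependent AUC — sizes at which the checks are sharp while the full run
stays at desk scale. The coordinate-descent path uses 50 penalties down to
1% of the data-derived maximum with tolerance defaults; active-set size is
weakly monotone along the path up to one-step solver wobble, and the test
suite allows exactly that. The Breslow log partial likelihood is computed
with a global max-shift for numerical stability. Cutoff enumeration and the
IPCW weights are exact (no binning); the permutation check of the log-rank
p-value uses 10,000 relabelings and agrees with the asymptotic p to within
Monte-Carlo error.

## Known limitations

- The packaged signature is fixed truth from its source publication; its
  exact pair list is not refittable from scratch because the original fold
  assignments are unknown, and the package does not attempt to regenerate
  its 0.184 cutoff.
- Lasso selection among correlated pairs is unstable by nature; the recovery
  guarantee is statistical (rate over seeds), not per-run.
- The IPCW estimator assumes censoring independent of the score; strongly
  score-dependent censoring would bias both AUC and cutoff.
- `read_expression`'s zero-fraction gene filter is meant for FPKM-like
  RNA-seq input and should be disabled for microarray intensities.
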