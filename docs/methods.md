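# Methods

## Models

Two outcome families are supported on a common covariate representation
(an n × M molecular matrix X, optionally with a small unpenalized block of
clinical covariates):

* **Binary endpoint.** Logistic regression, logit P(y_i = 1 | x_i) =
  β₀ + x_iβ.  The loss is the negative binomial log-likelihood
  −L(β) = Σ_i [ln(1 + e^{η_i}) − y_i η_i].
* **Survival endpoint.** Cox proportional hazards, h(t|x) = h₀(t) e^{xα},
  observed as (Z_i, δ_i) with Z_i = min(T_i, C_i) and event indicator δ_i.
  The loss is the negative log partial likelihood with the **Breslow**
  approximation for tied event times: −PL(α) = −Σ_{δ_i=1} [η_i −
  ln Σ_{j: Z_j ≥ Z_i} e^{η_j}].  Breslow was chosen over Efron because it
  has the simplest pathwise-solver algebra and the two coincide for
  distinct event times; the baseline hazard h₀ is never estimated — the
  pipeline ranks and scores by the linear predictor only.

Three penalties: ridge λΣβ_j², lasso λΣ|β_j|, adaptive lasso
λΣ|β_j|/w_j with w_j = |β̂_j^{lasso}| from a first-stage CV-tuned lasso.
The absolute value in w_j is forced: a signed first-stage coefficient
would give a meaningless negative penalty.  Features with β̂_j^{lasso} = 0
receive an infinite penalty (exact zero, reported as excluded); hence the
adaptive active set is a subset of the lasso active set by construction.
An empty first-stage active set raises an explicit "nothing to refit"
signal rather than returning an empty model.

## Objective scaling and standardization

The internal objective is (1/n)·loss + λ·penalty.  An unscaled formulation
differs only by reparameterizing λ (λ_unscaled = n·λ_internal); the scaled
form keeps λ comparable across sample sizes and CV folds.  Continuous
covariates are standardized internally to zero mean and unit (1/n)
variance and coefficients are returned on the original scale; 0/1
indicator covariates are left unstandardized by default so a mutation
coefficient stays "log hazard ratio per altered sample" (a flag overrides
this).  Clinical covariates always carry penalty factor 0.  The logistic
intercept is never penalized; Cox models have no intercept.

## Solver

Outer iteratively-reweighted least squares around an inner cyclic
coordinate descent with soft-thresholding (numba-compiled, glmnet-style
active-set cycling: one full sweep to find the active set, inner sweeps
over the nonzero coordinates until stable, then a full sweep to confirm).
IRLS working weights/responses: p(1−p) and η + (y−p)/w for logistic; the
per-subject score and diagonal Hessian of the Breslow partial likelihood
for Cox, with weights floored at 1e-9 to guard flat regions.  Convergence:
relative coefficient change < 1e-7, capped at 1e5 total sweeps, with the
converged flag reported rather than silently assumed.  Solutions are
certified by the l1 KKT conditions: |(1/n)∇_j loss| ≤ λ·pf_j + tol for
inactive coordinates, equality with sign agreement for active ones; the
acceptance suite requires violations < 1e-6 across a grid of datasets and
λ values.

**λ path.** λ_max = max_j |(1/n)∇_j loss at the null model| / pf_j (the
null model fits only the unpenalized block), then 100 log-spaced values
down to ε·λ_max with ε = 1e-2 when p > n else 1e-3, fitted with warm
starts.  Ridge has no finite all-zero point, so its path starts at
100·λ_max.  Pathwise fits may stop early once the fit explains > 99% of
the null deviance or the per-step gain drops below 1e-5 — the saturated
tail carries no statistical information and dominates run time.

**CV tuning.** 10-fold stratified CV (by class, or by event indicator for
Cox) on the full-data λ grid; criterion = mean held-out binomial deviance
(logistic) or the Verweij–van Houwelingen cross-validated partial
likelihood deviance −2[PL_all(β̂_{−k}) − PL_{−k,train}(β̂_{−k})] (Cox),
which remains defined when held-out risk sets are tiny.  λ̂ is the
minimizer; exact ties break toward the larger (more parsimonious) λ.
Path fits inside tuning use a relaxed coordinate tolerance of 1e-5 — the
deviance curve is insensitive at that precision — and the final model is
always refit at 1e-7.  The 10-fold default applies to λ tuning only; the
prediction-power CV below defaults to 5 folds, and the two are
deliberately separate knobs.

## Screening

Optional first step: per feature, a single-covariate logistic or Cox fit
(statsmodels / lifelines) and its two-sided Wald p-value — Wald rather
than likelihood-ratio because thousands of univariate fits are the common
case and the Wald statistic needs no second fit.  Zero-variance features,
non-convergent fits and fits showing separation (|coef| or SE above 100)
are flagged with a missing p, excluded from the test count m and never
selected.  Benjamini–Hochberg step-up selection at q (default 0.05):
largest rank i with p_(i) ≤ i·q/m, selecting all p ≤ p_(i); BH-adjusted
q-values (monotone minima of m·p_(i)/i, capped at 1) are reported
alongside, and thresholding q-values at q reproduces the step-up
selection exactly.

## Post-selection inference

For a Gaussian response y ~ N(μ, σ²I), the lasso selection event
{active set E, signs s} at fixed λ is the affine set {Ay ≤ b} built from
the KKT conditions (sign consistency of the active block; the inactive
subgradient bound).  For each j ∈ E the contrast η_j = X_E(X_E'X_E)⁻¹e_j
targets the E-restricted least-squares projection; conditional on the
event and on the component of y orthogonal to η_j, η_j'y is N(·, σ²‖η_j‖²)
truncated to an interval [V⁻, V⁺] obtained by intersecting the constraint
rows.  The reported p-value is the two-sided truncated-Gaussian pivot
2·min(F, 1−F), computed in log space from whichever tail is better
conditioned so that far-out intervals do not underflow.  Intervals
narrower than 1e-8 standard deviations are flagged and the p reported
missing.

Logistic and Cox fits enter through the one-step weighted least-squares
linearization at the solution: X̃ = W^{1/2}X_s, ỹ = W^{1/2}z with (W, z)
the IRLS quantities at the fitted coefficients and X_s the internal
standardized design.  At convergence the weighted working problem shares
its lasso KKT system with the fitted GLM, so the selection event carries
over verbatim.  The unpenalized block (intercept, clinical covariates) is
profiled out by orthogonal projection in the weighted metric; for Cox
there is no intercept and the linear predictor is used in internal
(shift-free) coordinates, which the partial likelihood cannot distinguish.
The adaptive lasso is reduced to a plain lasso event by rescaling each
design column by its adaptive weight.  Noise scale: σ = 1 for the
logistic/Cox working models (the standard GLM convention); for the pure
Gaussian family σ is estimated from active-set residuals when n exceeds
the active-set size, else fixed at 1.  Inference is performed at the
CV-chosen λ although the conditioning formally assumes λ fixed in
advance — the standard practical compromise, stated rather than hidden.
Calibration is verified empirically: on no-signal Gaussian problems the
pooled selective p-values of selected features are uniform (KS test),
while naive post-selection z-tests on the same fits concentrate near zero.

## Prediction-power cross-validation

Stratified K folds (default 5; K = 1 is the documented no-op returning a
"not performed" report).  Each fold refits the entire configured pipeline
— screening, λ tuning, first-stage lasso for adaptive fits — on the
training portion only; a canary test (a noise feature made perfectly
predictive only in one fold's held-out rows) checks that the held-out
fold's metrics are bit-identical, i.e. nothing leaks.  Binary models:
accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP) at a strict
score > threshold rule (default 0.5 on the probability scale; any
threshold/scale pair can be supplied, e.g. a log-odds cutoff such as
0.34), and Mann–Whitney AUC with ties counted ½.  Survival models:
Harrell's C over comparable pairs (an event anchors a pair with any
longer-surviving subject; tied risks count ½).  Metrics are aggregated as
the unweighted mean over folds; AUC is stored in [0, 1] and scaled ×100
only in the display form.  A fold in which screening or selection leaves
no features predicts a constant score (AUC 0.5), which is the honest
null behaviour rather than an error.

## Synthetic data

The generator draws what the pipeline expects to see in tumor cohorts:
0/1 mutation indicators with per-gene prevalence uniform on 1–10% (or a
given value), and unit-normal expression Z-scores, so ~4.6% of entries
exceed the |Z| > 2 abnormality cutoff.  Binary outcomes follow the sparse
logistic model; survival times are exponential with hazard h₀·e^{xβ}
(h₀ = 0.1 by default) under independent exponential censoring, giving the
closed-form censoring fraction c/(c + h₀·E[e^{xβ}]) used to calibrate,
e.g., ~30% censoring.  Ground truth (support, coefficients, achieved
censoring) is always emitted so tests and users never re-derive it.  What
the generator does **not** emulate: correlated features (LD-like blocks,
co-expression modules), non-proportional hazards, informative censoring,
batch structure.  Tests passing on these draws therefore certify the
estimator and its inferential calibration under the assumed models, not
robustness to real-data violations of them.

## Data conventions and edge cases

Z-score binarization uses the strict rule |z| > cutoff (default 2), so
z = ±2 itself is normal — the literal reading of "above 2 or below −2".
Prevalence filtering keeps features altered in ≥ the given fraction of
samples (1% is the usual mutation cutoff, 2% for expression
abnormalities), erroring explicitly when nothing survives.  Expression
data can enter either as binarized abnormality indicators (default, since
selection results are then "abnormality associated with outcome") or as
raw Z-scores via a flag.  Missing covariate cells are an error by
default; an opt-in flag drops affected features — imputation is
deliberately not offered.  Sample alignment intersects IDs across matrix,
outcome and clinical table, reorders to matrix order and reports dropped
IDs.  Classification uses strict inequality, so a score exactly at the
threshold maps to class 0.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to make each property
measurable with comfortable margins on one core: solver-vs-oracle
comparisons at p ≤ 2 (n = 60) against Nelder-Mead minimization of the
written objective; KKT grids at n = 120, p = 40; BH against the step-up
definition on 1000 random p-vectors (m ≤ 50); FDR control with m = 1000
null features × 200 replicates; support recovery at n = 400, p = 100 with
five ±1.5 signals over 20 seeds; selective-inference calibration on 500
Gaussian working problems (n = 100, p = 10); null prediction metrics at
n = 200 over 10 seeds.  Full-cohort results from public tumor datasets
(hundreds of samples × tens of thousands of features) are out of scope
here: they require the original matrices, and nothing in the package is
specific to the sizes above.

## Known limitations

* No elastic-net mixing, group/fused penalties, or parallel solvers.
* Selective inference for logistic/Cox rests on the one-step Gaussian
  linearization; only that working model's own calibration is verified.
* Conditioning ignores the CV choice of λ (see above).
* Breslow ties only; heavy tying plus Efron-based external comparisons
  will disagree slightly.
* The CLI reads whole matrices into memory; cohorts beyond ~10⁵ features
  × 10³ samples deserve chunked IO that is not implemented.
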