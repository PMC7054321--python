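# penomics

Penalized regression analysis of high-dimensional molecular alteration data
— mutations, copy-number changes, expression Z-scores — against clinical
endpoints, for statisticians and computational biologists working with
tumor profiling cohorts where features far outnumber patients.

## What it does

Given a samples × features molecular matrix and a clinical table carrying
either a binary outcome (e.g. invasive vs. non-invasive subtype) or a
right-censored survival outcome, the package fits

* **logistic regression** — minimize −L(β)/n + λ·P(β), with L the binomial
  log-likelihood of logit P(y=1|x) = β₀ + xβ, and
* **Cox proportional hazards regression** — minimize −PL(α)/n + λ·P(α),
  with PL the Breslow log partial likelihood of h(t|x) = h₀(t)·exp(xα),

under three penalties P: **ridge** (Σβ²), **lasso** (Σ|β|) and **adaptive
lasso** (Σ|β_j|/w_j with w_j = |β̂_j^lasso| from a first-stage lasso;
features the first stage zeroes out are excluded).  The l1 penalties
perform variable selection; λ is chosen by K-fold cross-validated deviance
(Verweij–van Houwelingen cross-validated partial likelihood for Cox).

Around the fits the package provides:

* **FDR screening** (`screen`) — per-feature univariate Wald p-values,
  Benjamini–Hochberg step-up selection at q (default 0.05);
* **post-selection inference** (`postsel`) — "correct" p-values for
  lasso-selected features via polyhedral conditioning: the selection event
  is an affine set on the (working) Gaussian response, giving a truncated
  normal pivot for each selected coefficient;
* **prediction-power CV** (`validate`) — stratified K-fold (default 5)
  refitting the whole pipeline per fold; accuracy/sensitivity/specificity/
  AUC for binary models, Harrell's C-index for survival models;
* **reporting** (`report`) — hazard/odds ratios exp(β̂), model
  serialization, scoring and thresholded classification of new samples;
* **simulation** (`simulate`) — seeded generators for sparse mutation
  matrices, Gaussian Z-score matrices, logistic outcomes and exponential
  proportional-hazards survival with independent censoring, with ground
  truth emitted alongside.

## Worked example

```python
import numpy as np
from penomics import penalized as pen, postsel, report, validate
from penomics.simulate import SimulationSpec, simulate_dataset

D, truth = simulate_dataset(SimulationSpec(
    n_samples=400, n_features=100,
    true_support=(0, 1, 2, 3, 4), true_coefficients=(1.5, -1.5, 1.5, -1.5, 1.5),
    seed=11))

spec = pen.PenaltySpec("lasso", "cv")
lam, curve = pen.cv_tune("logistic", D, spec, n_folds=10, seed=1)
fit = pen.fit("logistic", D, spec, lambda_=lam)
print("lambda:", round(lam, 4), "active:", fit.active_set)

si = postsel.selective_pvalues("logistic", D, fit)
print(report.effect_sizes(fit, p_values=dict(zip(si.feature_ids, si.p_values)))
      .to_frame().head(6).to_string(index=False))

cfg = validate.PipelineConfig("logistic", penalty="lasso")
print(validate.kfold_cv(D, cfg, n_folds=5, seed=1).display())
```

prints

```
lambda: 0.0194 active: ['G0000', 'G0001', 'G0002', 'G0003', 'G0004', 'G0010', 'G0012', 'G0016', 'G0017', 'G0024', 'G0026', 'G0029', 'G0034', 'G0046', 'G0050', 'G0080', 'G0085']
feature_id  coefficient  odds_ratio      p_value
     G0000        0.915       2.497 2.703615e-12
     G0001       -1.312       0.269 5.680651e-17
     G0002        0.940       2.560 7.364984e-05
     G0003       -0.846       0.429 4.682682e-08
     G0004        0.832       2.297 2.913751e-05
     G0010       -0.015       0.985 3.072211e-01
{'accuracy': 0.84..., 'sensitivity': 0.8292..., 'specificity': 0.8512..., 'auc': 92.02...}
```

The CV-tuned lasso recovers all five planted signals (plus a few small
false positives, as expected for `lambda.min`); the selective p-values are
tiny for the true signals and unremarkable for the extras; held-out AUC is
printed ×100 in the display form.

The same workflow is available from the shell:

```bash
penomics simulate --n 400 --p 100 --support 5 --family logistic --seed 7 --out data/
penomics run --matrix data/matrix.tsv --clinical data/clinical.tsv --no-binarize \
    --family logistic --penalty lasso --fdr --q 0.05 --seed 7 --out results/
```

## Layout

```
src/penomics/
  dataio.py     read/validate matrices & clinical tables, Z-score binarization,
                prevalence filtering, sample alignment
  screen.py     univariate Wald p-values + Benjamini–Hochberg selection
  penalized.py  IRLS + coordinate-descent solver, lambda paths, CV tuning,
                adaptive weights, KKT certification
  postsel.py    polyhedral-lemma selective p-values
  validate.py   pipeline K-fold CV, AUC / confusion metrics / C-index
  report.py     effect sizes, model JSON, scoring, classification
  simulate.py   seeded synthetic data with ground truth
  cli.py        `penomics` command-line interface
docs/methods.md  model and implementation notes
```
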