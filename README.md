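# panelgfr

Robust estimation of glomerular filtration rate (GFR) from a panel of
eight endogenous filtration markers — five metabolites (creatinine,
acetylthreonine, pseudouridine, tryptophan, phenylacetylglutamine) and
three low-molecular-weight proteins (cystatin-C, β2-microglobulin, β-trace
protein).

## The problem

Estimating equations map blood concentrations of filtration markers to an
estimated GFR (eGFR). Each marker's concentration also depends on
*non-GFR determinants* — generation, tubular handling, extra-renal
elimination — and these vary across patients and populations. When an
equation developed in one population is applied elsewhere, two failure
modes appear:

1. **Outlying predictors** — in an individual patient, one or two markers
   can be pushed far from the value their GFR implies (medication,
   inflammation, muscle wasting), corrupting the estimate.
2. **Systematic shifts** — a whole application population can have a
   different marker–GFR relationship, biasing every estimate.

`panelgfr` implements the statistical machinery to address both, on the
log scale where the models `log mGFR ~ β₀ + Σₘ βₘ log xₘ` are linear:

* **Outlier detection** in application rows, referenced to the development
  population: univariate 1st/99th-percentile flags; multivariate
  Winsorization that shrinks a row with squared Mahalanobis distance
  D² = (x−μ)ᵀΣ⁻¹(x−μ) above the χ²₈(0.99) quantile back onto the
  tolerance ellipse; and consistency screening, which keeps the six of the
  eight single-marker GFR estimates with the smallest sum of absolute
  pairwise differences.
* **Robust estimation** from the trustworthy markers: a
  correlation-weighted trimmed mean of single-marker estimates; K-nearest-
  neighbor marginalized estimation (average of full-model predictions over
  development neighbors matched on the clean markers); and screened linear
  regression (the development OLS refit on exactly the clean subset — all
  C(8,6) = 28 six-marker models can be pre-fitted).
* **Contamination simulation** — mean (±s·σ shifts), variance (×√9
  deviation inflation), or mean+variance contamination of chosen markers
  in a random 10% of application rows, to emulate populations with
  elevated outlier rates.
* **Two-step transfer learning** for tailoring the equation to a small
  target population: an L1-penalized fit on pooled transferable sources
  plus target data gives rough coefficients w; an L1-penalized fit of the
  target residuals gives a bias correction δ; the final model is
  β = w + δ. An internal 3-fold cross-validation decides which source
  populations are transferable, guarding against negative transfer.
* **Synthetic multi-study cohorts** with the structure of real pooled GFR
  databases (eight studies, realistic marker levels, calibrated
  marker–mGFR correlations, between-study slope heterogeneity), so every
  method is testable without access to patient data.

Everything composes with scikit-learn: `PanelGFREstimator` and
`TransferGFREstimator` are standard fit/predict regressors.

## Worked example

```python
import numpy as np
from panelgfr import (PanelGFREstimator, ContaminationSpec, contaminate,
                      default_design, generate_multistudy, rmse_log, p30)

# development data: synthetic eight-study cohort (n = 3,499)
dev = generate_multistudy(default_design(seed=7))
X, y = dev.X(), dev.y()          # log markers, log mGFR

# application data: fresh draw, then contaminate pseudouridine and
# cystatin-C (the two strongest markers) in a random 10% of rows
app = generate_multistudy(default_design(n_total=1000, seed=8))
X_app, y_app = app.X(), app.y()
spec = ContaminationSpec(markers=("pseudouridine", "cystatin_c"), seed=9)
X_contam, mask = contaminate(X_app, X.mean(axis=0), X.std(axis=0, ddof=1), spec)

naive = PanelGFREstimator(detection="none", estimator="naive").fit(X, y)
robust = PanelGFREstimator(detection="consistency", estimator="screened").fit(X, y)

mgfr = np.exp(y_app)
for name, model in [("naive 8-marker OLS", naive), ("consistency + screened", robust)]:
    egfr = model.predict_gfr(X_contam)
    print(f"{name:24s} RMSE(log) = {rmse_log(mgfr, egfr):.3f}   P30 = {100*p30(mgfr, egfr):.1f}%")
```

prints

```
naive 8-marker OLS       RMSE(log) = 0.231   P30 = 88.5%
consistency + screened   RMSE(log) = 0.195   P30 = 88.1%
```

The naive model's log-scale RMSE is inflated by the 100 contaminated rows;
dropping each row's two most inconsistent markers and predicting from the
six-marker development model recovers most of the loss. P30 (the share of
estimates within 30% of measured GFR) barely moves because it is dominated
by the uncontaminated bulk.

The command line mirrors the library: `panelgfr simulate | fit | detect |
estimate | contaminate | evaluate | learning-curve | combined` (see
`panelgfr --help`).

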