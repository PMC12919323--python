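# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `standgrowth`, including what the synthetic
generator does and does not emulate.

## Curve catalogue and fitting scales

The eight basic forms (linear, logarithmic, reciprocal, quadratic, cubic,
S-curve, growth, logistic) are the standard curve-estimation catalogue for
height–diameter and age–diameter allometry. Seven of them are linear in
their parameters after a transform and are fitted by ordinary least
squares on the transformed design: powers of x, ln x, 1/x as predictors,
and — for the S-curve y = exp(b₀ + b₁/x) and the growth form
y = exp(b₀ + b₁x) — ln y as the response. This is the convention of
classic curve-estimation software, and the R²/F/p of those two forms are
therefore computed **on the log scale** and tagged `fit_scale="log"` in
every `FitResult`. An original-scale nonlinear re-fit of any form is
available (`fit(form, x, y, prefer_closed_form=False)`), and the logistic
is always fitted by nonlinear least squares.

The nonlinear backend is trust-region least squares (scipy `trf`) with
ftol = xtol = gtol = 1e-10 and a function-evaluation budget of
500 × (n_params + 1). Starting values are data-driven: the closed-form
transform fit for linearizable forms; for the logistic, b₁ = 1.05·max y,
b₃ = median x, and b₂ from the slope of the logit linearization
ln(b₁/y − 1) ~ x; multivariate forms start at the basic fit with covariate
coefficients 0. On non-convergence the fitter makes up to three seeded,
jittered restarts and keeps the lowest SSE, returning `converged=False`
with the best parameters rather than raising. Logistic fits with b₁ ≤ 0 or
b₂ = 0 (improper sigmoid, e.g. on a constant response) are flagged
non-converged, never silently accepted.

Degrees of freedom follow one convention throughout: df₁ = number of
non-intercept parameters, df₂ = n − df₁ − 1,
F = (R²/df₁)/((1−R²)/df₂), p from the upper F tail. For the
(intercept-free) logistic this gives df₁ = 3; published tables of this
kind are inconsistent on the point (df₁ of 1 or 2 for identical
parameter counts), so the package documents its convention instead of
replicating any.

## Multivariate extensions

Each basic form has a counterpart with 1–3 covariate terms appended after
the base parameters: extra additive terms for the polynomial-type forms,
terms inside the exponent for S-curve/growth, and inside the denominator
for the logistic — exactly where the printed multivariate equations of
this literature put them. With all covariate coefficients zero the
extension evaluates bit-for-bit identically to its basic form (a tested
identity). The logistic denominator can become non-positive at adverse
parameter values; the fitter assigns such points a large penalty residual
so the search moves away rather than crashing.

In the workflow, linearizable extensions are fitted by OLS **on the same
scale as their basic form**, which makes the nesting guarantee exact: the
multivariate modelling-set R² cannot fall below the basic one. The
multivariate logistic is fitted by NLS initialized at the basic fit.

## Screening and selection

Covariates are ranked by Pearson correlation with DBH. The default rule
ranks by signed r (descending); the observed practice this reproduces
keeps DEM (0.52), P (0.41) and TXn (0.41) ahead of larger-|r| negative
covariates, which a principled `absolute` option would instead admit.
Ties break by catalogue order. VIF uses an intercept in each auxiliary
regression; exact collinearity raises a named error.

`select_best` takes the maximum modelling-set R² among converged fits,
breaking exact ties by fewer parameters, then catalogue order; an optional
`tie_tol` widens "tie" to the resolution of a 3-decimal report table.
Validation metrics are reported but never used for selection.

**Model identifiability.** Users should not expect the selected form to
"recover the truth" at inventory noise levels. Fitting each competitor to
the *noiseless* generating curves over each species' own predictor
distribution shows best-competitor RMS approximation biases of 0.00–0.10
response units against residual SDs of 0.8–3.1: the discriminability
index n·(bias/σ)² stays ≤ 1.4 at n = 400 for every generating curve in
the default profiles. Two forms that close are statistically
indistinguishable — the logistic's lower tail *is* a growth curve, and
over a 2:1 predictor range the S-curve, reciprocal and logarithm nearly
coincide — so selection among them is decided by noise, whatever the
selection statistic. The test suite asserts form recovery only where
curves are well separated (wide predictor spans, low noise); at the
default study conditions recovery rates are reported, not guaranteed.

## Validation metrics

On the hold-out partition: ME = mean(ŷ−y), MRE = mean((ŷ−y)/y) (flagged
undefined if any y = 0), RMSE = √(Σ(ŷ−y)²/(n−p)) with p the number of
independent variables (1 basic, 1 + covariates multivariate), and
R² = 1 − SSE/SStot with the hold-out mean in SStot. Hold-out R² may be
negative and is not clamped; RMSE is nonnegative by construction (the
negative values occasionally seen in published tables of this kind are
typesetting errors and cannot arise here). Residual direction is
predicted − measured throughout.

## Partitions

`split_table` uses largest-remainder rounding so integer partition sizes
always sum to n (70/30 gives exactly (70, 30) at n = 100; 70/15/15 gives
(70, 15, 15)), optionally within each species. Identical seed and input
give the identical partition. Whether the original survey's split was
species-stratified is not recorded anywhere; stratification is on by
default in the workflow and is a flag, not a finding.

## Neural baseline

One hidden layer of 10 tanh units, linear output, trained full-batch by
Levenberg–Marquardt on the L2-penalized squared loss (decay 0.001 on
weights, not biases). Describing LM with a "learning rate" is an unusual
hybrid; the package reads the stated rate (0.01) as the initial damping
parameter, adapted ×10/÷10 on step rejection/acceptance, and also provides
a fixed-damping Gauss–Newton variant and scikit-learn's Adam-trained MLP
(`optimizer="adam_fallback"`) as the first-order reading. Inputs and
response are z-scored on the training split only (tanh saturates on raw
DBH/elevation scales). Early stopping watches the validation split
(patience 20, max 1000 epochs) and restores the best-validation weight
snapshot. Training is deterministic given the seed: initialization is the
only random element, and the Jacobian is analytic. Because the headline
accuracy convention for such baselines is ambiguous between r and r², the
metrics dict reports both (`test_r2`, `test_r`).

## Synthetic generator

Each species profile holds: a truncated-normal stand-age distribution
(published mean/SD/min/max in years), the published optimal age–DBH and
DBH–height equations as generating curves, additive Gaussian noise SDs,
and covariate targets. Generation is: ages → DBH = curve(age) + noise →
height = curve(DBH) + noise, resampling non-positive draws; covariates are
drawn conditionally on DBH by a Gaussian copula, ρ·z_DBH + √(1−ρ²)·ε,
affinely scaled into their physical ranges (midpoint ± range/6), which
preserves the target Pearson correlation exactly in population.

Choices worth knowing:

* The published summary tables label their dispersion column "Standard
  Error", but at n ≈ 2193 an SE of 6.58 cm on a mean of 20.47 cm would be
  absurd; the generator treats those values as sample SDs.
* Noise SDs default to 15% of the species' mean response, which lands the
  true form's modelling R² in the 0.6–0.8 band typical of published fits;
  they are per-profile configurable (`with_noise`).
* MixedWood's heterogeneous composition is emulated by a ±2 m
  two-component offset mixture in the height residual process, driving its
  DBH–height R² to the weak (≈0.05–0.15) level real mixed stands show.
  The mixture is part of the noise model and is disabled together with
  `noise_sd_height=0`, so zero-noise draws lie exactly on the curves and
  end-to-end parameter recovery is exact.
* The TXn covariate's published mean is sign-inconsistent with its own
  min/max; the scaling uses the min/max range only.
* Composing the published Spruce age distribution with the published
  age–DBH curve gives E[DBH] = 19.70 cm by quadrature, ~3.7% below the
  published sample mean of 20.47 cm — the printed curve and the printed
  moments are not mutually consistent. The generator follows the
  construction (curve + mean-zero noise); calibration tests check the
  sample mean against the construction's own expectation sharply, and
  against the published mean loosely.

What the generator does **not** emulate: spatial plot layout, repeated
measurement, climate time series, measurement rounding, or any causal
effect of covariates on growth (covariates are correlational only, which
is all the screening stage assumes). Passing tests therefore demonstrate
the correctness of the machinery under the stated generative model, not
the field validity of any fitted equation.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 50 datasets per form for
the closed-form oracle; 10 random draws per form (n = 120) for zero-noise
recovery; n = 500 at 5%-of-mean noise for noisy recovery; 50 (tests) or
20 (script) replicates of n = 400 stands for selection consistency;
n = 10 000 for generator calibration; n = 200 for the neural sanity
checks; and the published per-species sample sizes (2193 + 940 Spruce down
to 19 + 8 Sand jujube) for the full-pipeline run.
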