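# standgrowth

Stand growth-curve modelling for plot-level forest inventories.

Forest managers routinely need tree height (hard to measure) from diameter
at breast height, DBH (easy to measure), and expected DBH from stand age.
`standgrowth` implements the classic curve-estimation workflow used for
this in growth-and-yield studies of arid-basin forests — spruce, poplar,
sand jujube, *Populus euphratica* and heterogeneous mixed stands — and is
aimed at quantitative ecologists who want that workflow reproducible,
seeded and testable end to end.

## What it computes

**Basic curve forms.** Eight candidate regressions of a response *y*
(height, or DBH) on a single predictor *x* (DBH, or stand age):

| form | equation |
|---|---|
| linear | y = b₀ + b₁x |
| logarithmic | y = b₀ + b₁ ln x |
| reciprocal | y = b₀ + b₁/x |
| quadratic | y = b₀ + b₁x + b₂x² |
| cubic | y = b₀ + b₁x + b₂x² + b₃x³ |
| S-curve | y = exp(b₀ + b₁/x) |
| growth | y = exp(b₀ + b₁x) |
| logistic | y = b₁ / (1 + exp(−b₂(x − b₃))) |

Forms linear in their parameters after a transform are fitted by OLS on the
transformed design (the S-curve and growth forms regress ln y, and their R²
is tagged with that scale); the logistic — or any form on request — is
fitted by trust-region nonlinear least squares with data-driven starting
values. Every fit reports R², F, df₁/df₂ and p.

**Covariate screening.** Per-plot environmental covariates (elevation DEM,
annual precipitation P, the cold-extreme index TXn, and further climate
indices) are ranked by Pearson correlation with DBH; the top three enter
the selected basic form as additive terms (inside the exponent or logistic
denominator where applicable), after a variance-inflation-factor check
(VIF = 1/(1−R²ⱼ), threshold 5).

**Hold-out validation.** A seeded 70/30 split; on the 30% partition each
model reports ME = mean(ŷ−y), MRE = mean((ŷ−y)/y),
RMSE = √(Σ(ŷ−y)²/(n−p)) with p the number of independent variables, and
R² = 1 − SSE/SStot.

**Neural baseline.** A 10-unit single-hidden-layer tanh network trained by
full-batch Levenberg–Marquardt with L2 weight decay 0.001, a 70/15/15
split and validation-based early stopping; accuracy is reported on the
test split.

**Synthetic inventories.** `standgrowth.synthetic` generates five-species
stand tables with known generative truth — published age distributions,
optimal growth equations as generating curves, and Gaussian-copula
covariates hitting target DBH correlations (0.52, 0.41, 0.41) — so the
whole chain is testable without survey data.

## Worked example

```python
import standgrowth as sg

table = sg.generate_inventory(seed=42, n_per_species=400)
result = sg.run_workflow(table, sg.WorkflowConfig(seed=0))

print("selected covariates:", result.screening.selected)
for rep in result.reports:
    if rep.relation != "dbh_height":
        continue
    vm = rep.validation["basic"]
    print(f"{rep.species:18s} best={rep.best.form.family:11s} "
          f"R2={rep.best.r2:.3f}  holdout RMSE={vm.rmse:.3f}")
```

prints

```
selected covariates: ['dem', 'txn', 'p']
Spruce             best=cubic       R2=0.695  holdout RMSE=1.897
Poplar             best=s_curve     R2=0.717  holdout RMSE=1.924
MixedWood          best=cubic       R2=0.065  holdout RMSE=2.246
SandJujube         best=s_curve     R2=0.711  holdout RMSE=0.821
PopulusEuphratica  best=s_curve     R2=0.334  holdout RMSE=1.225
```

Reading this: all three screened covariates cleared the VIF threshold;
Poplar and SandJujube's DBH–height relations are recovered as the
saturating S-curve that generated them, with modelling R² in the 0.6–0.8
band typical of inventory data; MixedWood's weak fit (R² = 0.065) reflects
its deliberately heterogeneous composition; and where forms are nearly
indistinguishable over a species' observed DBH span, a flexible polynomial
can edge out the generating curve by a sliver of R² (Spruce here) — see
`docs/methods.md` on model identifiability. Hold-out RMSE is in metres.

The same steps are available from a shell:

```
standgrowth simulate --n-per-species 400 --seed 42 --out synth.csv
standgrowth run --input synth.csv --relation both --seed 0 --out reports/
standgrowth nn --input synth.csv --relation age-dbh --species Spruce \
    --covariates dem,p,txn --seed 3
```

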