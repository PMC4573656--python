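# allocov

Recovery of missing fit statistics for allometric tree-biomass equations,
and propagation of those statistics to model-error estimates of
above-ground biomass (AGB) at the tree, species, and per-hectare level.

## The problem

National and regional forest carbon accounts predict the biomass of every
inventory tree with published allometric equations, AGB = f(DBH, HT; b̂).
Reporting an uncertainty for such model-dependent estimates requires the
residual variance σ²ₑ and the coefficient covariance matrix cov(b̂) of the
original fit, via the delta method:

    V(ÂGBⱼ) = σ²ₑ + gⱼᵀ cov(b̂) gⱼ ,   gⱼ = ∂f(xⱼ|b)/∂b |_{b=b̂} .

For a large share of published equations those statistics were never
printed — often only the sample size n and a coefficient of determination
R² survive. `allocov` builds *substitutes* from exactly that minimum plus
inventory samples of the population the equation will be applied to:

- **basic** — B without-replacement samples of size n; per sample,
  σ̃²ₑ = V(f(x|b̂))·(1/R² − 1) and cõv(b̂) = σ̃²ₑ (FᵀF)⁻¹ with F the
  gradient matrix; averaged over B;
- **weighted** — (FᵀWF)⁻¹ with sum-to-one weights ∝ 1/DBH² (or inverse
  inclusion probabilities), replicating a weighted original fit;
- **refit** — a parametric bootstrap with scaled-t pseudo-residuals
  (multiplicative gamma errors when additive residuals would produce
  negative biomass), averaging the per-fit covariance matrices;
- **robust** — a sandwich (FᵀF)⁻¹(Σ ẽᵢ² gᵢgᵢᵀ)(FᵀF)⁻¹ with heavy-tailed
  simulated residuals, t with ⌊0.5·n⌋ df — the recommended prudent choice.

The package ships the source equations as a built-in registry (German
BWI-1987 species-group equations; Mexican NFI species equations), seeded
synthetic population generators matched to the printed inventory
summaries, Box's M and F-ratio comparison tests, and error-budget
propagation (Eq. above, species means σ̃²ₑ/n_s + ḡᵀcõv ḡ, per-hectare
λ̂²V(ĀGB) + ĀGB²V(λ̂)). Details, assumptions and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Recover the missing covariance matrix for the *Guazuma ulmifolia* log-log
equation (published fit: n=18, adjusted R²=0.97) from a synthetic
inventory matched to the printed NFI moments (DBH 12.9 ± 5.1 cm), then
propagate it to the model error of the species-mean biomass:

```python
import numpy as np
from allocov import (RecoveryConfig, SpeciesPanel, robust_recovery,
                     get_equation, species_error_budget)
from allocov.synthetic import PopulationSpec, generate_population

eq, fit = get_equation("guazuma_ulmifolia")
trees = list(generate_population(
    PopulationSpec("guazuma_ulmifolia", 2000, 12.9, 5.1, 5.5, 2.4, seed=42)))

stats = robust_recovery(eq, trees, fit, RecoveryConfig(B=800, seed=42))
panel = SpeciesPanel("guazuma_ulmifolia", trees, stem_density=201.0)
budget = species_error_budget(eq, panel, stats)
```

Output:

```
guazuma_ulmifolia: log(AGB) = -1.62 + 2.12 log(DBH)   (n=18, R2=0.97)
recovered residual SD (log scale): 0.14
recovered cov(b):
[[ 0.0512 -0.0202]
 [-0.0202  0.0081]]
MC error of det (%): 3.82
mean AGB (kg/tree): 52.0
relative model error of mean AGB (%): 3.45
```

Reading the numbers: the recovered covariance matrix lives on the log
scale of the fitted model; the strong negative off-diagonal (correlation
≈ −0.99) is the usual intercept-slope collinearity of log-log allometry.
At B=800 replicates the Monte Carlo error in the determinant of the
recovered matrix is below 4 %. The mean predicted AGB of 52 kg/tree
carries a model error of about 3.5 % — the residual-variance contribution
is divided by the 2000 panel trees, so the coefficient uncertainty
dominates.

The same workflow is available from a shell:

```bash
allocov recover --registry guazuma_ulmifolia --trees trees.csv \
        --method robust --B 800 --seed 42 --out recovered.json
allocov propagate --registry guazuma_ulmifolia --recovered recovered.json \
        --trees trees.csv --species guazuma_ulmifolia \
        --stem-density 201 --out budget.json
allocov compare --a recovered.json --b reference.json --n 18 --out mtest.json
allocov simulate --scenario scenario.yaml --out outdir/
```

`simulate` runs the full fit–hide–recover–compare validation experiment:
fit an equation to a random sample (the "actual" statistics), hide the
covariance, recover substitutes from the remaining population, test each
against the actual matrix with Box's M, and propagate all of them to
relative errors of the mean AGB.

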