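# hetvar

Two-step REML analysis of **genetic heterogeneity of residual variance**
("micro-environmental sensitivity") in pedigreed populations, with a Monte
Carlo simulator for studying the sampling behaviour of the two-step
estimates.

Quantitative geneticists use this kind of analysis to ask whether uniformity
of a trait — weight gain, carcass weight, litter size — is itself heritable:
do some families produce intrinsically more variable offspring than others,
and could selection on "dispersion breeding values" make production more
uniform?

## The model

Phenotypes follow a multiplicative exponential dispersion model

    y_ij = b_m(i) + a_m(j) + exp((b_v(i) + a_v(j)) / 2) · ε_ij,  ε ~ N(0,1)

with contemporary-group effects on the mean (b_m) and the log residual
variance (b_v), and bivariate animal breeding values (a_m, a_v) with
additive variances σ²_a and σ²_Av,exp and genetic correlation r_mv, spread
over the pedigree via the numerator relationship matrix **A**.

Estimation is in two REML steps:

1. **Trait model** (`hetvar.step1`): animal model for y with CG fixed,
   direct (and optionally maternal) additive effects, and residual variance
   either homoscedastic (HOM) or per sire family (HET).
2. **Dispersion model** (`hetvar.step2`): the same animal-model machinery on
   ln(ê²), the log squared residuals of step 1. Its additive variance
   estimates σ²_Av,exp; its BLUPs are dispersion EBVs.

Derived parameters (`hetvar.gparams`): σ²_AV = σ²_ê²·(exp(σ²_Av,exp) − 1) on
the residual-variance scale, evolvability Ev = σ_AV/σ²_ê, heritability of
residual variance h²_v = σ²_AV/(2σ⁴_P + 3σ²_AV), and the sire-EBV
correlation r̂_mv between mean and dispersion.

## Worked example

```python
from hetvar import (
    SimulationDesign, GeneticParameters, simulate_dataset,
    EditRules, Step1ModelSpec, apply_edit_rules, reml_fit,
    build_response, fit_dispersion_model, summarize_genetic_parameters,
)

# 2 generations x 20 sires x 1000 dams, 2000 records, Ev ~ 53%
ds = simulate_dataset(
    SimulationDesign.small(),
    GeneticParameters(sigma2_a=200.0, sigma2_Av_exp=0.25, r_mv=0.0),
    seed=11,
)
edited, _ = apply_edit_rules(ds.records, EditRules(), ds.pedigree)

s1 = reml_fit(edited, ds.pedigree, Step1ModelSpec(residual_structure="het_sire"))
s2 = fit_dispersion_model(build_response(s1.fit.residuals), edited, ds.pedigree)
g = summarize_genetic_parameters(s1, s2)
print(f"sigma2_a      = {s1.sigma2_a:.1f}")
print(f"sigma2_Av_exp = {s2.sigma2_Av_exp:.3f}")
print(f"Ev            = {g.ev_pct:.1f}%")
print(f"h2_v          = {g.h2v_pct:.2f}%")
```

prints

```
sigma2_a      = 153.7
sigma2_Av_exp = 0.369
Ev            = 66.8%
h2_v          = 8.23%
```

The additive variance of the trait is recovered near its true 200 kg²
(individual replicates scatter ±~18%), while the dispersion variance 0.369
overestimates the true 0.25 — the documented upward bias of the two-step
approach when step 1 allows sire-family-specific residual variances. With a
HOM first step the same data give an *under*estimate. The Monte Carlo
harness (`hetvar.montecarlo.run_grid`) replicates this whole pattern over a
scenario grid and summarises bias, r̂_mv and dispersion-EBV accuracies by
animal group.

A command-line interface mirrors the library: `hetvar simulate`,
`fit-step1`, `fit-step2`, `params`, `cv`, `mc`, and `pipeline` (simulate →
step 1 → step 2 → parameters, with a content-hashed manifest). All
configuration lives in one YAML file; see `hetvar --help`.

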