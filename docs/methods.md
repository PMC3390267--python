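# Methods

## The problem

In most animal-breeding mixed models the residual (environmental) variance is
assumed constant across genotypes. There is, however, accumulating evidence
that micro-environmental sensitivity is itself partly under genetic control:
some families are intrinsically more variable than others. If so, uniformity
of a trait can be improved by selecting on breeding values for the residual
variance. `hetvar` implements the classical two-step REML route for
quantifying this "genetic heterogeneity of residual variance" in pedigreed
populations, together with a Monte Carlo harness for studying the sampling
behaviour of the two-step estimates.

## Generative model

Phenotypes follow a multiplicative exponential dispersion model,

    y_ij = b_m(i) + a_m(j) + exp((b_v(i) + a_v(j)) / 2) * eps_ij,
    eps_ij ~ iid N(0, 1),

where contemporary group (CG) `i` acts on the mean through `b_m` (kg) and on
the log residual variance through `b_v` (log-kg²), and animal `j` carries a
bivariate breeding value `(a_m, a_v) ~ MVN(0, G_mv)` with

    G_mv = [[sigma2_a,              r_mv * sqrt(sigma2_a sigma2_Av_exp)],
            [  ...   ,              sigma2_Av_exp                      ]].

Under this model the expected residual variance of a group is
`exp(b_v) * exp(sigma2_Av_exp / 2)` (lognormal mean), and the additive
variance of the residual variance itself is the lognormal variance identity

    sigma2_AV = sigma2_e^2 * (exp(sigma2_Av_exp) - 1),

so the genetic coefficient of variation of residual variance — the
*evolvability* Ev = sigma_AV / sigma2_e = sqrt(exp(sigma2_Av_exp) - 1) — is
scale-free. The three simulated dispersion variances 0.01, 0.09 and 0.25 map
to Ev of about 10%, 31% and 53%.

## Two-step estimation

**Step 1** fits the trait animal model y = Xb + Z1 a + Z2 m + Wc + e by
AI-REML, with the CG factor fixed, direct additive effects always present,
optional maternal additive and maternal permanent-environment effects
(direct–maternal covariance fixed at zero), and a residual that is either a
single variance (HOM) or one variance per sire family (HET). Records whose
sire is unknown (possible only when editing is bypassed) share one pooled
residual class under HET.

**Step 2** treats the log squared residual ln(ê²) of each record as a noisy
measurement of its log residual variance and fits the same animal-model
machinery to this response (HOM residual, same CG factor, no covariates).
The additive variance of the response estimates `sigma2_Av_exp`; its BLUPs
are dispersion EBVs. If the first-step residuals were exactly the true
residuals, ln(ê²) = (b_v + a_v) + ln(chi²_1), a left-skewed response
(skewness ≈ −1.54, the log-chi-square shape) whose sampling variance
psi'(1/2) ≈ 4.93 forms the bulk of the step-2 residual. A cube-root
transform (ê²)^(1/3) is offered as an alternative response closer to
normality.

Headline parameters: evolvability as above; the heritability of residual
variance h²_v = sigma2_AV / (2 sigma_P⁴ + 3 sigma2_AV) (the regression of
dispersion breeding values on squared phenotypes); and, because the genetic
correlation between mean and dispersion is not directly estimable in two
steps, the Pearson correlation r̂_mv between sire EBVs for the mean and for
ln(ê²), restricted to sires with more than 50 progeny.

## REML engine

The engine maximises the restricted likelihood over variance components by
average-information (AI) updates with step-halving, falling back to an EM
step (monotone by construction) whenever an AI proposal leaves the parameter
space or decreases the likelihood. Design choices that matter:

- **Mixed-model equations.** Assembled sparse; factorised by dense Cholesky.
  At the equation sizes this package targets (10²–10⁴) a dense factorisation
  plus LAPACK `dpotri` inverse is faster and far simpler than sparse
  selected-inverse machinery, and the full inverse supplies every trace the
  scores and EM updates need exactly.
- **Positivity.** Components are floored at 1e-8 × var(y). A component at
  the floor whose score points outward is treated as a boundary solution:
  frozen out of updates and convergence checks, and flagged on the fit.
- **Convergence.** |Δ logL| < 1e-7 and relative component change < 1e-5, or
  a scaled score max |∂logL/∂log θ| < 1e-4 when a boundary component makes
  the likelihood evaluation numerically noisy. Cap: 200 iterations;
  non-convergence raises, carrying the last iterate.
- **Identifiability.** The first level of each fixed factor is absorbed as
  reference; a pivoted QR names confounded columns when p ≤ 2000 (beyond
  that, structural singularity surfaces in the factorisation).
- **AIC/BIC.** p counts free variance components only (solutions are not
  parameters under REML); the BIC sample size is n − rank(X). The familiar
  qualitative ordering (AIC prefers HET, BIC prefers HOM) emerges from these
  definitions on simulated data.
- **Standard errors** come from the inverse AI matrix at the solution.

Step-2 zero residuals are floored at the 1e-6 quantile of the positive
squared residuals (an observed value, so the smallest legitimate residual is
never floored); floored records are counted and reported, never silently
absorbed. Likelihood-ratio tests of a single boundary-tested variance
component use the equal mixture of a point mass at zero and chi-square(1);
the naive chi-square p-value is reported alongside.

## Synthetic populations

The generator reproduces a beef-cattle-like recording structure: a base
population of 100 sires and 5000 dams; five generations of 5000 recorded
offspring each (25 000 records); every sire has 50 offspring per generation,
split as 10 progeny in each of 5 CGs (100 CGs per generation, each holding
the progeny of 5 sires); every dam has one offspring per generation; 20% of
sires and dams are replaced each generation by randomly chosen
previous-generation animals of the correct sex; random mating, no selection.
Base animals are unrecorded parents; every non-base animal has exactly one
record. Offspring sex is Bernoulli(0.5) — it matters only for replacement
eligibility. Breeding values descend by midparent average plus a Mendelian
term with covariance d_i · G_mv, d_i = 0.5 (1 − (F_s + F_d)/2) from the
pedigree's inbreeding; CG effects are drawn fresh per CG from U(300, 400) kg
and U(5.40, 5.80) log-kg².

With sigma2_a = 200 these defaults give a trait with mean 350 kg, phenotypic
variance near 480 kg² and heritability near 0.41 (at sigma2_Av_exp = 0.09).
A master seed feeds independent named substreams (pedigree, CG effects,
breeding values, residual draws), so datasets are bit-reproducible and the
pedigree stream can be varied independently of the effect stream.

What the generator does *not* emulate: selection and non-random mating,
overlapping age structure, maternal effects on either scale, sex-specific
variances, and environmental noise acting on the residual variance beyond
the CG effect. Passing tests therefore demonstrate correct behaviour of the
estimators under the exponential model's own assumptions, not robustness to
the confounding present in field data.

## Problem sizes for replicated studies

Replicated two-step analyses run at a reduced preset (`design_small`): 2
generations × 20 sires × 1000 dams = 2000 records, which preserves the
family-size structure (50 progeny per sire per generation) while keeping a
full two-step replicate around half a minute. The test suite uses this
preset with 3–5 replicates per scenario; the acceptance script uses 5
replicates for the dispersion-bias and accuracy scenarios and 25 replicates
for the step-1 recovery check.

The recovery of sigma2_a deserves a caveat. With only ~24 sire families the
dominant noise in sigma2_a_hat is the realized variance of the sire breeding
values themselves (sampling SD ≈ sqrt(2/24) ≈ 29% of sigma2_a), giving a
per-replicate SD around 20% that no feasible replicate count averages away
at this preset; replicate batches also suggest a small positive
finite-sample tendency (mean deviation of order +5–10% over 45 replicates).
A correctly-specified control (sigma2_Av_exp = 0) reproduces the same
per-replicate estimates almost exactly, so this is a property of the scale,
not of the dispersion heterogeneity or the estimator: the engine matches a
dense-likelihood oracle to numerical precision, and tight mean-recovery
statements (a few %) are only meaningful at the full design.

Scale matters for the dispersion parameters themselves: with 20 sire
families instead of 100, step 2 sees far fewer family-level observations, so
the HOM attenuation of sigma2_Av_exp is somewhat deeper (about −55% at 0.09
and −78% at 0.25 in pilot runs, against −50% at the full 25 000-record scale) and the
HET overestimation at 0.01 is somewhat milder (about 20-fold against
30-fold). Reducing the design below ~20 families makes the dispersion
variance essentially unidentified and the summaries meaningless, which is
why the bias-pattern checks do not run on anything smaller.

## Known limitations

- The two-step approach is known to be biased for dispersion parameters
  (that bias pattern is precisely what the Monte Carlo harness measures);
  one-step structural or double-hierarchical models are out of scope.
- Unknown-parent groups and genomic relationship matrices are not modelled.
- The h²_v formula and its delta-method SE follow the standard
  regression-on-squared-phenotypes derivation; both are isolated in a single
  function so an alternative convention can be swapped in.
- HET fits one residual variance per sire family with no smoothing; with
  families below ~30 progeny the family variances themselves are noisy and
  the step-2 inflation grows accordingly.
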