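# Methods

`blfdr` implements a covariate-modulated empirical-Bayes procedure for
deciding which brain-connectivity links differ between two groups of
subjects, when each link carries a functional-connectivity (FC) test
statistic and a structural-connectivity (SC) test statistic. This note
records the model, the algorithmic choices, the synthetic-data conditions,
and the limits of what the tests demonstrate.

## The two-group mixture model

For link *i* of *m*, let `t_f[i] >= 0` be the absolute FC statistic and
`t_s[i] >= 0` the absolute SC statistic. The model is a two-group mixture
for `t_f` in which `t_s` enters twice:

- **Null component.** `t_f | null ~ FoldedNormal(0, sigma0_sq)`. With zero
  location the folded normal is the half-normal, so the implementation uses
  the single-term density multiplied by two; a regression test confirms the
  two-term reflection form agrees. The null does not depend on `t_s`.
- **Alternative component.** `t_f | alt ~ mu1 + Gamma(shape, beta)` with
  `shape = exp(alpha0 + alpha1 * t_s)` and fixed location
  `mu1 = 0.674`, the median of the standard folded normal. The density is
  exactly zero for `t_f <= mu1`: a statistic at or below the standard
  half-normal median is treated as null outright (ties at `mu1` included),
  which bounds the alternative away from zero and resolves the
  identifiability of the mixture without strong parameter assumptions.
- **Prior odds.** `P(alt | t_s) = logistic(gamma0 + gamma1 * t_s)`, so
  structural evidence shifts each link's prior probability of being
  disrupted.

The per-link posterior null probability ("BLfdr value")

```
BLfdr(t_f, t_s) = pi0(t_s) f0(t_f) / [pi0(t_s) f0(t_f) + pi1(t_s) f1(t_f, t_s)]
```

is computed in log space with a stable log-sum-exp; it is exactly 1 below
the alternative support and decays to 0 as `t_f` grows (the Gaussian null
tail loses to the gamma tail for any `beta > 0`).

## Priors

Weakly informative throughout, chosen so the priors regularize without
dominating: `beta ~ Gamma(1, 1)` and `sigma0_sq ~ Inverse-Gamma(3, 2)`
(both mean 1, variance 1), and independent bivariate normals
`alpha ~ N2(0, I)`, `gamma ~ N2(0, I)`. Conventional "non-informative"
Gamma(0.001, 0.001)-type priors are deliberately avoided: they concentrate
mass at zero with a heavy tail, destabilize the Gibbs sampler, and make the
posterior diffuse.

## Gibbs sampler

Each sweep updates, in order: latent indicators `w` (exact Bernoulli full
conditional, forced to 0 off the alternative support), `alpha` and `gamma`
(one multiple-try Metropolis step each), then `beta` (conjugate Gamma) and
`sigma0_sq` (conjugate Inverse-Gamma). The conditional for `beta` is
`Gamma(a_beta + sum_alt shape_i, b_beta + sum_alt (t_f - mu1))`; for
`sigma0_sq` it is `Inverse-Gamma(a_sigma + n0/2, b_sigma + sum_null t_f^2 / 2)`.

**Multiple-try Metropolis.** Proposals are symmetric bivariate-t
perturbations with `nu = 4` degrees of freedom (three finite moments, heavy
enough tails for occasional long jumps). Five candidates are drawn per step;
one is selected with probability proportional to its target density; a
reference set of four fresh points around the selection plus the current
point completes the standard MTM acceptance ratio. With one try the step
reduces to ordinary Metropolis, and the test suite confirms both variants
share their stationary distribution and that MTM moments match 2-D grid
integration of the target. Proposal scales adapt toward 20-50% acceptance
during burn-in only and are frozen afterwards, so retained draws come from a
fixed kernel.

**Initialization.** `alpha = (0, 0)`, `beta = 0.1`, `sigma0_sq = 1`, and an
initial null proportion of 0.94: links at or above the 0.94 empirical
quantile of `t_f` (and above `mu1`) start in the alternative component, and
`gamma` starts at the logistic regression of those indicators on `t_s`
(marginal-frequency fallback if the regression is degenerate or separable).

**Protocol.** The full protocol runs three chains of 325,000 iterations,
25,000 burn-in, thinning 100 - 9,000 pooled draws; posterior medians are
the point estimates. A `desk` profile (3 x 20,000, burn 5,000, thin 10) and
a `quick` profile (1 x 2,000) serve interactive work and simulation studies.
Convergence is summarized by split-chain rhat and bulk ESS (arviz); rhat
above 1.1 warns but does not abort.

**Correctness evidence.** Beyond the grid-oracle tests of each conditional,
a Geweke successive-conditional test (alternating one Gibbs sweep with
re-simulation of data given the parameters, whose stationary parameter
marginals must equal the priors) passes for all six parameters. That test
runs with coefficient prior sd 0.5 and a small `t_s` spread: with wider
priors the chain visits gamma shapes below ~0.01 whose draws underflow
double precision onto the excluded support boundary `t_f = mu1`, a
floating-point limit of the data generator rather than a sampler defect.

## Decision rule and baseline

**Oracle rule.** Sort the per-link null probabilities ascending and reject
the largest prefix whose running mean is at most `q`; the mean posterior
null probability over the rejected set is then an estimate of the realized
FDR. Ties are broken by original index (stable sort). With no rejections
the false discovery proportion is defined as 0.

**Storey estimate.** `pi0_hat = #{p > lambda} / (m (1 - lambda))` at
`lambda = 0.025`, capped at 1.

**Covariate-free baseline (Lfdr).** The marginal density of the signed FC
statistics is estimated by Lindsey's method - histogram counts (120 bins)
modeled as Poisson with a degree-7 polynomial log mean (the degree is
reduced automatically on GLM failure) - and the empirical null
`N(delta0, sigma0^2)` with proportion `p0` comes from a quadratic fit to the
log density on the central 50% of mass (central matching under the zero
assumption). `lfdr = p0 f0 / f`, capped at 1. Known limitation: when
alternatives form isolated far-away modes, the low-degree polynomial fills
the valley between modes and central matching can underestimate `sigma0`,
producing anticonservative tail lfdr values. This is intrinsic to the
estimator class and is one reason the baseline's FDR inflates at small
sample sizes in the simulation study.

## Link statistics from subject data

FC matrices hold Pearson correlations (Fisher-Z transformed,
`atanh`); SC matrices hold tractography fiber counts (cube-root
transformed; zeros stay zero, no pseudo-count). Each of the `R(R-1)/2`
links is tested with a Welch (heteroscedastic) two-sample t statistic on
the transformed values. Optional subject-mean centering subtracts each
subject's across-link mean first; it removes any per-subject additive
offset exactly and stands in for the random subject intercept of a
mixed-effects formulation - with one observation per subject per link, the
between-group intercept contrast reduces to a two-sample location test.
The mixture model consumes absolute statistics; the baseline and the
tail-trimming rule use the signed ones.

## Synthetic studies

The generator emulates a small two-group study at the scale of an 87-ROI
parcellation: `m = 3741` links, `n` in {15, 25, 35, 45} per group. Truth
assignment: 1% of links non-null in both modalities, 1% FC-only, 1%
SC-only (floor of `frac * m`, i.e. 37 + 37 + 37), the rest null. Effect
sizes are drawn once per replicate - FC difference from U(0.055, 0.095) on
the Fisher-Z scale, SC difference from U(0.15, 0.35) on the cube-root
scale - and shared across that replicate's alternative links.

Observations are built on the transformed scales as
`baseline + subject intercept + group shift + error`, then mapped to raw
correlations (`tanh`) and fiber counts (cube), and pushed through the
standard link-statistic pipeline with subject centering. Default
conditions, chosen once as a realistic small-study regime and not revisited:

- baseline link means: FC ~ N(0.3, 0.1^2), SC ~ N(1.5, 0.5^2);
- subject intercept sd: 0.05 (FC), 0.15 (SC);
- per-link error sds: Gamma(shape 4) with mean 0.10 (FC) and 0.30 (SC);
  the disease group's errors are scaled by 1.2 (heteroscedastic, noisier
  patients). At `n = 15` this puts alternative links at |t| around 2 -
  weak-to-moderate signal, the regime where borrowing structural strength
  matters;
- FC-SC coupling `rho` in {0.1, 0.4, 0.9} acts on the bivariate subject
  random intercepts (`rho_on="subjects"`). An alternative placement on the
  per-observation error pair (`rho_on="errors"`) is available; it makes the
  null FC and SC statistics themselves correlated at ~rho, which at rho =
  0.9 feeds the FC noise directly into the SC covariate and collapses the
  mixture - useful as a stress case, not as the default study condition.

**Trimming.** The evaluation protocol reports the two-sided 10% trimmed
mean of the per-replicate FDP and sensitivity distributions, i.e. each
summary uses the central 80% of simulated data sets. A per-replicate
variant that deletes the top and bottom 10% of links by signed FC statistic
before fitting (`trim="links"`, `trim_study`) is implemented and tested,
but it removes exactly the strong alternatives and the rejection region -
under it the baseline never rejects and large-n FDR cannot approach `q` -
so it is not the default protocol.

**What the generator does not emulate.** Raw BOLD time series, tractography,
spatial structure among links (links are exchangeable given their truth
category), non-Gaussian measurement artifacts, and missing data. Passing
tests therefore show that the procedure behaves as designed when its
distributional assumptions hold approximately at realistic scale and noise;
they do not certify behavior on real imaging pipelines.

## Problem sizes used by the checks

The packaged checks scale the full protocol down, as the package's desk
profile: the simulation comparison runs 200 replicates per correlation
level (tests) or 70 (acceptance script) with single short chains (1,200
iterations, 400 burn-in, 3 tries per MTM step) instead of 10,000 replicates
with full chains; parameter recovery uses 20 (tests) or 12 (script) fits
with 2 x 7,000-iteration chains. Under these conditions the directional
result - lower small-sample FDR for the covariate-modulated procedure at
every correlation level - is stable, while absolute FDR levels carry
Monte-Carlo error of roughly +-0.02.

## Numerical choices and degenerate inputs

- All density work is in log space; membership probabilities use the
  logistic of a log-odds difference.
- Gamma-shape exponents are clamped at 500 before exponentiation; a
  non-finite MTM target gives a candidate zero weight.
- `t_f` exactly equal to `mu1` is null (support is strict inequality).
- Zero within-group variance in a link test: equal means give statistic 0,
  unequal means a large finite capped value with a warning.
- Correlations at |r| = 1 are clipped to 1 - 1e-7 before Fisher-Z, with a
  warning.
- `pi0_init = 1` starts every link in the null component and takes the
  marginal-frequency fallback for `gamma`.
- The folded-normal location is fixed at zero and not user-settable; no
  alternative component families are offered.

## Known limitations

- Posterior coverage is calibrated when the truth behaves like a prior draw
  (the Geweke test); for a fixed truth in the prior's tail - e.g. gamma
  rate near 2.2 under a Gamma(1, 1) prior with only ~180 alternative links
  to inform it - shrinkage places 95% intervals below nominal fixed-truth
  coverage for `alpha0` and `beta`. This is a property of weakly informed,
  weakly identified parameters, not of the sampler.
- The baseline's Lindsey density fit degrades on strongly multimodal
  statistic distributions (see above).
- Very small gamma shapes (below ~1e-2) cannot be simulated faithfully in
  double precision; the model should not be trusted in that corner of the
  parameter space.
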