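# blfdr — covariate-modulated Bayesian local FDR for brain connectivity

`blfdr` detects disrupted brain-connectivity links between two groups of
subjects (e.g. patients vs. controls) by letting structural connectivity
(SC) lend strength to the analysis of functional connectivity (FC). It is
aimed at small neuroimaging studies — ten to a few dozen subjects per
group, thousands of links — where standard multiple-testing corrections
either miss everything or let the false discovery rate (FDR) run away.

## The model

Each of the m = R(R−1)/2 links carries an absolute FC test statistic
t⁽ᶠ⁾ and an absolute SC test statistic t⁽ˢ⁾ (Welch t statistics on
Fisher-Z-transformed correlations and cube-root-transformed fiber counts).
The FC statistics follow a two-group mixture in which the SC statistic
modulates both the mixing weight and the alternative density:

    f(t⁽ᶠ⁾ | t⁽ˢ⁾) = π₀(t⁽ˢ⁾) f₀(t⁽ᶠ⁾) + π₁(t⁽ˢ⁾) f₁(t⁽ᶠ⁾ | t⁽ˢ⁾)

- null: f₀ = FoldedNormal(0, σ₀²) — a half-normal with unknown scale;
- alternative: f₁ = μ₁ + Gamma(shape, β) with shape = exp(α₀ + α₁ t⁽ˢ⁾)
  and μ₁ = 0.674 fixed at the median of the standard folded normal, so any
  statistic at or below μ₁ is null a priori;
- prior odds: π₁(t⁽ˢ⁾) = logistic(γ₀ + γ₁ t⁽ˢ⁾).

The per-link posterior null probability (the **BLfdr** value)

    BLfdr = π₀ f₀ / (π₀ f₀ + π₁ f₁)

is the Bayesian, covariate-modulated counterpart of Efron's local false
discovery rate. Parameters get weakly informative priors — Gamma(1, 1) on
β, Inverse-Gamma(3, 2) on σ₀² (both mean 1, variance 1), standard bivariate
normals on (α₀, α₁) and (γ₀, γ₁) — and are fitted by a Gibbs sampler with
multiple-try Metropolis steps for the two coefficient blocks. Rejections
come from the oracle rule: sort BLfdr values ascending and reject the
largest prefix whose running mean stays at or below the target level q,
which controls the FDR at q.

The package also ships the covariate-free baseline (`EfronLocalFdr`:
Lindsey density estimation plus central matching), the link-statistic
pipeline from subject-level connectivity matrices, a synthetic-study
generator with known truth, and a CLI (`blfdr simulate/fit/decide/
baseline/evaluate`). See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

Simulate a study at realistic scale (3,741 links, 15 subjects per group,
2% FC alternatives), fit the model, and decide at q = 0.2:

```python
from blfdr import (BayesianLocalFdr, EfronLocalFdr, SimulationDesign,
                   simulate_study, oracle_reject, score_decisions)

design = SimulationDesign(n_per_group=15, rho=0.4, seed=7)
study = simulate_study(design)

model = BayesianLocalFdr(preset="desk", random_state=0).fit(study.table)
print(model.summary_.table.round(3))

decision = model.decide(q=0.2)
scores = score_decisions(decision.rejected, study.truth_fc)
print(f"BLfdr: rejected {decision.k_rejections} links at q=0.2 "
      f"(FDP {scores['FDP']:.2f}, sensitivity {scores['sensitivity']:.2f})")

baseline = EfronLocalFdr().fit(study.t_f_signed)
res_b = oracle_reject(baseline.lfdr_, q=0.2)
scores_b = score_decisions(res_b.rejected, study.truth_fc)
print(f"Lfdr : rejected {res_b.k_rejections} links at q=0.2 "
      f"(FDP {scores_b['FDP']:.2f}, sensitivity {scores_b['sensitivity']:.2f})")
```

Output:

```
           median   q2.5  q97.5   rhat       ess
alpha0     -0.284 -0.735  0.282  1.005   417.340
alpha1      0.231  0.096  0.347  1.001  1569.397
beta        0.624  0.400  0.940  1.004   449.288
gamma0     -3.362 -4.217 -2.646  1.001   394.769
gamma1      0.381  0.051  0.668  1.000   899.670
sigma0_sq   1.015  0.933  1.087  1.001   645.677
BLfdr: rejected 50 links at q=0.2 (FDP 0.42, sensitivity 0.39)
Lfdr : rejected 70 links at q=0.2 (FDP 0.49, sensitivity 0.49)
```

Reading it: the null scale is recovered (σ₀² ≈ 1.02, CI excludes neither
the generator's unit-variance statistics nor the mild disease-group
inflation), γ₁ > 0 says links with stronger SC evidence get higher prior
odds of being FC-disrupted, and all rhat values are at 1.0. At n = 15 the
signal is weak, so both procedures overshoot the nominal q = 0.2 on a
single replicate — but the Bayesian model overshoots less, which is its
point: averaged over hundreds of replicates it keeps the realized FDR
consistently below the covariate-free baseline at every FC–SC correlation
level (see the tests and the script below).

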