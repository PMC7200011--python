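# envnet

Environment-dependent analysis of bipartite ecological network architecture.

Antagonistic (host–parasite, plant–herbivore) and mutualistic
(plant–pollinator, seed-dispersal, …) communities are both described by
binary bipartite incidence matrices, and their architectures — summarized
by spectral metrics — overlap so strongly that the interaction class
cannot be read off the network alone. `envnet` implements the
environment-dependent resolution of this puzzle: because network
architecture co-varies with the local environment *with opposite sign in
the two classes* (a Simpson's-paradox configuration), adding a single
environmental covariate (temperature variability, the standard deviation
of the annual temperature fluctuation in °C) makes the classes
statistically separable, while randomized architectures remain
indistinguishable. The package also quantifies *why*: temperature
variability has opposite per-class effects on network stability.

## What it computes

For a binary incidence matrix **B** (rows = guild A, columns = guild B):

- **Architecture metrics.** λ1 and λ2, the two largest eigenvalues of the
  bipartite adjacency `[[0, B], [Bᵀ, 0]]` (equivalently the top singular
  values of **B**), as nestedness and modularity indicators, corrected by
  two null models into relative errors `1 − λ̄ⁿᵘˡˡ/λ`:
  Erdős–Rényi (`er`, preserves size and connectance exactly) and
  configuration (`cm`, preserves both degree sequences exactly, sampled
  by curveball trades).
- **Differentiation.** A feature table (three relative errors, optionally
  the environment) → z-scoring → PCA with 68% coverage ellipses →
  cross-validated discriminant accuracy with a permutation test, under
  three criteria: *separability* (classes), *scalability* (sub-classes
  nest within classes), *specificity* (ER-randomized architectures sit at
  chance — scaled on the randomized table, since randomization makes the
  class label a collider between environment and metrics).
- **Stability.** λ1, λ2 (dynamical stability) and Ω, the relative size of
  the feasibility domain of intra-guild competition: the solid angle of
  the cone `{A·x : x > 0}` where `A = (1−ρ)I + ρ·Â` and
  `Â_ij = (B Bᵀ)_ij / √((B Bᵀ)_ii (B Bᵀ)_jj)` is the normalized
  shared-partner overlap. Ω is computed as a Gaussian positive-orthant
  probability with covariance `(AᵀA)⁻¹` (Genz quasi-Monte Carlo), with a
  direct Monte Carlo oracle for cross-checking.
- **Regression.** Per-class standardized OLS of each stability metric on
  temperature variability with size and connectance as covariates, plus
  an opposite-sign check and an ER-randomized control.
- **Synthetic data.** A generator for nested/modular bipartite networks
  (`p_ij ∝ exp(−ν(r_i + c_j))`, rescaled to a target connectance) and for
  whole confounded communities in which the environment–architecture
  coupling has opposite sign per class while marginal metric
  distributions overlap — so the entire analysis runs and is tested
  without any external data.

## Worked example

```python
from envnet.experiments import (
    run_separability_experiment, run_stability_regression_experiment)

sep = run_separability_experiment(seed=1)
print(f"metrics only:       accuracy {sep.accuracy_metrics_only:.3f}")
print(f"with environment:   accuracy {sep.accuracy_with_environment:.3f}")

reg = run_stability_regression_experiment(seed=1)
print(f"beta_T lambda1:  mut {reg.coef_temp_mut_lambda1:+.2f}"
      f" / ant {reg.coef_temp_ant_lambda1:+.2f}")
print(f"beta_T omega:    mut {reg.coef_temp_mut_omega:+.2f}"
      f" / ant {reg.coef_temp_ant_omega:+.2f}")
```

prints

```
metrics only:       accuracy 0.638
with environment:   accuracy 0.890
beta_T lambda1:  mut +0.69 / ant -0.78
beta_T omega:    mut -0.42 / ant +0.40
```

Reading: on 200 synthetic networks whose metric distributions overlap
across classes, the three architecture metrics alone classify near
chance (0.64), while adding temperature variability lifts a quadratic
discriminant to 0.89 — the Simpson structure made visible. The
regressions recover opposite temperature effects: more variable
environments are associated with higher λ1 (more dynamical stability)
but lower feasibility Ω in mutualistic networks, and the reverse in
antagonistic networks; both patterns vanish when architectures are
ER-randomized.

The same pipeline is available from the shell:

```sh
envnet simulate --out nets/ --n-per-class 50 --seed 7
envnet differentiate --networks nets/ --with-env --seed 7
envnet run --demo --out results/ --seed 7
```

## Real data

`envnet.network_io` reads incidence CSVs in the web-of-life.es labelled
dialect (header row/column of species names; weighted records are
binarized at > 0) plus a metadata table (`id, interaction_class,
sub_class, latitude, longitude, <environment columns>`), and screens
environmental variables for multicollinearity (`screen_collinearity`,
default |r| > 0.7). Point `envnet run --config cfg.yaml` at such a
directory with `mode: real`.
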