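# Methods

This note documents the models, estimators and design choices behind
`envnet`, in the order the pipeline runs them.

## Architecture metrics

The unit of analysis is a binary bipartite incidence matrix **B**
(m × n, rows = guild A). "Eigenvalues of the interaction matrix" are
defined on the symmetric bipartite adjacency `[[0, B], [Bᵀ, 0]]`, whose
positive spectrum equals the singular-value spectrum of **B**. This
convention guarantees real λ1 ≥ λ2 ≥ 0 and matches the spectral-radius
treatment of nestedness: at fixed size and fill, λ1 grows as links
concentrate into a nested core, and λ2 grows when links concentrate in a
second, separate block (modularity). λ2 is the second-largest adjacency
eigenvalue (= σ2(B)), not the second largest in absolute value. Raw λ1,
λ2 scale strongly with size S = m + n and connectance C = L/(m·n), which
are sampling-biased quantities, so the classification features are
null-corrected relative errors (below), not the raw eigenvalues.

## Null models

Two randomizations, each preserving a different invariant exactly:

- **Erdős–Rényi (`er`).** The L links are re-placed uniformly at random
  among the m·n cells without replacement. Shape and exact link count
  are preserved — the conditioned model, not independent Bernoulli(C).
  Empty rows or columns in replicates are allowed and kept; pruning them
  would silently change S.
- **Configuration (`cm`).** Curveball trades between random row pairs:
  the columns held by exactly one of the two rows are pooled and
  redistributed, preserving both degree sequences exactly. Trades are
  preferred over single checkerboard swaps for mixing speed. Each
  replicate is an independent chain from the empirical matrix with a
  burn-in of 5·L trades and one draw per chain; uniformity over the
  fiber is verified by goodness-of-fit against brute-force enumeration
  on small margins. Exact (not in-expectation) degree preservation is
  the deliberate reading of "degree distribution preserved".

The corrected metric is the relative error `1 − mean(λ_null)/λ` — the
fraction of the empirical eigenvalue not explained by the null — with
R = 100 replicates per model by default and the ensemble mean (not
median) as the summary. Negative values are legal. λ2 = 0 (rank-one
matrices) makes the λ2 relative error undefined; such networks are
excluded from feature tables with a logged count. The three features are
`1 − λ1^cm/λ1`, `1 − λ1^er/λ1`, `1 − λ2^er/λ2`.

## Stability metrics

λ1 and λ2 index dynamical stability (larger = more stable). Structural
stability is the relative feasibility-domain size Ω of intra-guild
competition. The competition matrix for the row guild is built from
shared-partner overlap: `O = B·Bᵀ`, normalized to unit diagonal
`Â_ij = O_ij/√(O_ii·O_jj)`, then blended with the identity,
`A(ρ) = (1−ρ)·I + ρ·Â`, ρ ∈ [0, 1), which guarantees positive
definiteness and parameterizes interspecific competition strength
(default ρ = 0.5; ρ = 1 is refused when Â is rank-deficient, where Ω
would degenerate to 0). This construction is the package's documented
default, flagged as a choice rather than asserted as canonical; the
same applies to reporting Ω per guild (default: rows) with a
both-guilds option (geometric mean as headline).

Ω is the fraction of the unit sphere of intrinsic growth-rate
directions admitting a feasible equilibrium, i.e. the solid angle of
`{A·x : x > 0}`. Since a uniform direction is `z/‖z‖` with z standard
normal and membership is `A⁻¹z > 0`, Ω equals the positive-orthant
probability of N(0, (AᵀA)⁻¹). The default estimator applies the Genz
separation-of-variables transform to that orthant integral over
scrambled Sobol points (10 independently scrambled batches of 2¹¹ by
default; the standard error is the batch spread). The transform is
exact for diagonal A — Ω(I_S) = 2⁻ˢ with zero variance — and accurate
to ~1e-5 in low dimensions. A direct Monte Carlo membership estimator
is retained permanently as the independent oracle. Degenerate S = 1
input returns the half-line convention Ω = 0.5, flagged with a warning.
Because Ω decays roughly geometrically in guild size, regressions use
the size-normalized `ω = Ω^(1/S_guild)` by default so the size covariate
is not encoded twice.

## Differentiation criteria

Features are z-scored (sample sd, n−1; the scaler records its reference
data explicitly), embedded by PCA (components sign-fixed by making the
largest-magnitude loading positive), and summarized per class by 68%
coverage ellipses (chi-square(2 df) quantile radius — the bivariate
normal convention). Separation is quantified, not judged visually:
repeated stratified cross-validation (3 × 5-fold) of a Gaussian
discriminant, a permutation p-value from 199 label shuffles, and the
Jaccard overlap of the two class ellipses on the PC1–PC2 plane.

**Why the default discriminant is quadratic.** The environment-dependent
hypothesis is precisely that the environment–architecture coupling has
opposite sign in the two classes. In (E, metrics) space the classes then
form an X: their means can coincide while their covariances differ in
orientation. A linear discriminant is provably blind to this structure —
the pooled covariance is symmetric in the two orientations, so any
linear boundary's accuracy is capped near the marginal accuracies
(simulations in this package put LDA at 0.47–0.61 where a quadratic rule
reaches 0.9). QDA — the Gaussian class-conditional model with
class-specific covariances — is the minimal classifier consistent with
the structure under test; `classifier="lda"` is kept as an option for
comparison, and the accuracy metric itself should be read as this
package's operationalization of "separation", not a canonical one.

**Specificity and the collider.** The specificity control replaces each
network by one ER randomization, recomputes the relative errors with
fresh null ensembles, and re-runs separability *with the environment
included*. Randomization severs the environment → architecture path, so
any remaining separation could only come from the environment's sampling
bias. Crucially, the feature scaler is fit on the randomized table:
after randomization the class label is a collider between environment
and metrics, and importing the empirical scaling carries the empirical
expectations into the randomized analysis — effectively conditioning on
the collider and manufacturing a spurious environment–metric
association. The scaling reference is therefore an explicit, mandatory
field; the empirical-scaler variant exists only as a flagged
anti-pattern for demonstration.

**Scalability** compares sub-class centroids on the PC plane: pass means
every sub-class centroid is on average closer to same-class sub-class
centroids than to other-class ones. Sub-classes with fewer than 3
members are excluded with a warning; a single sub-class per class
degrades to class-level distances and is flagged.

## Regression

Each stability response (λ1, λ2, ω) is regressed per interaction class
by OLS on temperature variability with size and connectance as
covariates; all variables standardized, so coefficients are comparable
across responses. Separate per-class fits (matching the two point sets
being contrasted) are the default; a pooled fit with a
class × temperature interaction is provided as a robustness variant.
1-SE and 2-SE intervals are exported for interval plots. The
opposite-sign check requires both temperature coefficients to exceed
2 SEs with opposite signs. The randomized control recomputes stability
on ER-randomized matrices and refits; the opposite-sign pattern is
expected to disappear.

## Synthetic generator

`generate_structured_network` draws B by independent Bernoulli sampling
of `p_ij = min(s·exp(−ν(r_i + c_j))·block_ij, 1)` with r, c the
normalized row/column ranks, the scale s solved by bisection so the
expected connectance hits the target (any target in (0,1) is reachable
because the capped mean is monotone in s with supremum 1). ν = 0 is
ER-like; increasing ν deepens the nested core, and the λ1 relative
error rises monotonically with ν (a property test); an optional
k-block within/between odds ratio adds modular structure. The family
itself is a modelling choice: any generator with a tunable λ1
relative-error gradient would serve, so it is validated only through
its calibration and monotonicity properties.

`generate_confounded_set` is the reference community. Per network:
class → sub-class → environment E ~ Normal(class mean, sd) → nestedness
`ν = ν0_class + b_class·(E − class mean) + noise`, truncated at 0 →
size, connectance → matrix. Default conditions: 100 networks per class;
guild sizes uniform 10–30; connectance anchored inversely to size within
0.1–0.3 with jitter (mirroring the empirical tendency of larger webs to
be sparser, and avoiding the small-and-sparse corner where spectral
metrics of a single realization are mostly noise); E: mean 4.0 °C
(mutualistic) vs 4.15 °C (antagonistic), sd 2.0 °C; couplings
b = +0.6/−0.6 per °C; baselines ν0 = 2.6/1.85; structural noise 0.15.
Centering the coupling on the class mean keeps marginal metric
distributions overlapping while within-class E–metric correlations are
≈ ±0.9 — the Simpson structure. The class baseline offset (mutualistic
networks more nested, consistent with the comparative literature) keeps
metrics-only classification near 0.6, well inside "not separable", and
the environment sampling bias is deliberately mild: its direction
(antagonistic networks from more variable climates) matters for realism,
but its magnitude is kept below statistical detectability at n = 200 so
the specificity control isolates architecture rather than geography.

What the generator does *not* emulate: empirical size/connectance joint
distributions of real compilations, spatial autocorrelation, sampling
effort gradients, weighted interactions, or any mechanism linking
temperature to architecture — the coupling is phenomenological. Passing
tests therefore demonstrate that the *pipeline* detects (and refuses to
hallucinate) the confounded structure when present at realistic
signal-to-noise, not that real communities carry that structure.

An intrinsic limit worth knowing: with single-realization networks of
guild size 10–30, the spectral relative errors carry irreducible
sampling noise (sd ≈ 0.03–0.05), which caps any classifier — the Bayes
rate of the default confounded community is ≈ 0.89–0.91 (estimated by
large-sample nearest-neighbour classification on 5,000 generator
draws). Cross-validated QDA attains that ceiling; reported accuracies
around 0.89 ± 0.02 on 200 networks are the information limit of these
conditions, not an estimator deficiency.

## Numerical conventions

- Seeds are explicit everywhere; ensembles derive per-replicate seeds
  from `numpy.random.SeedSequence`. Reruns with the same configuration
  are bit-identical.
- Curveball trades run in a numba kernel (~10⁷–10⁸ trades per full
  experiment); null-ensemble eigenvalues use batched LAPACK SVD.
- Relative errors with λ2 ≤ 1e-10 are treated as undefined (NaN).
- The permutation p-value uses the add-one estimator
  `(1 + #{perm ≥ obs})/(1 + N)`.
- Ellipse overlap is polygonal (256-gon) intersection-over-union.
- Reference experiment sizes (60 networks/class and 10 randomized
  replicates for the stability regressions; 2¹¹-point Sobol batches for
  Ω there) are chosen so a full acceptance run completes in minutes
  while every conclusion is comfortably beyond its decision threshold.
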