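"""Synthetic bipartite networks with tunable architecture and confounding.

Two generators:

* :func:`generate_structured_network` draws a single binary network from a
  nested-block family: interaction probability decays exponentially with
  the (normalized) row and column ranks at rate ν — ν = 0 is
  Erdős–Rényi-like, large ν is strongly nested — optionally multiplied by
  a within-block factor for modular structure, and rescaled so the
  expected connectance hits a target.

* :func:`generate_confounded_set` draws a community of networks with the
  class–environment–architecture structure the analysis is designed to
  expose: each class (antagonistic / mutualistic) samples an environmental
  value E (temperature variability, °C), and the nestedness strength is
  coupled to E with a class-specific slope — opposite signs by default —
  so that the *marginal* architecture distributions of the two classes
  coincide while the joint (metrics, E) distribution separates them
  (a Simpson's-paradox configuration).  A class-dependent environment mean
  emulates the geographic sampling bias of real compilations (antagonistic
  networks over-sampled from more variable climates) and can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from envnet.errors import GenerationError, ParameterError
from envnet.network_io import DEFAULT_ENV_VAR, InteractionNetwork, NetworkSet

MUTUALISTIC = "mutualistic"
ANTAGONISTIC = "antagonistic"


@dataclass
class StructureParams:
    """Parameters of a single structured network draw.

    nu >= 0 controls nestedness (0: homogeneous); ``modularity_blocks``
    with ``block_ratio`` > 1 concentrates links within k diagonal blocks.
    """

    m: int
    n: int
    connectance_target: float
    nu: float = 0.0
    modularity_blocks: int = 1
    block_ratio: float = 1.0
    seed: int = 0
    id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ParameterError("guild sizes must be >= 1")
        if not 0 < self.connectance_target < 1:
            raise ParameterError("connectance_target must be in (0, 1)")
        if self.nu < 0 or not np.isfinite(self.nu):
            raise ParameterError("nu must be finite and >= 0")
        if self.modularity_blocks < 1 or self.block_ratio < 1:
            raise ParameterError("need modularity_blocks >= 1 and block_ratio >= 1")
        if self.connectance_target * self.m * self.n < 1:
            raise ParameterError("expected link count below 1")


def _rank_weights(params: StructureParams) -> np.ndarray:
    """Unnormalized cell weights exp(−ν(r_i+c_j))·block_factor."""
    m, n = params.m, params.n
    r = np.arange(m) / max(m - 1, 1)
    c = np.arange(n) / max(n - 1, 1)
    W = np.exp(-params.nu * (r[:, None] + c[None, :]))
    k = params.modularity_blocks
    if k > 1 and params.block_ratio > 1:
        rb = (np.arange(m) * k) // m
        cb = (np.arange(n) * k) // n
        W = W * np.where(rb[:, None] == cb[None, :], params.block_ratio, 1.0)
    return W


def _calibrate_probabilities(W: np.ndarray, target: float) -> np.ndarray:
    """Scale weights so that mean(min(s·W, 1)) equals the target connectance.

    mean(min(s·W, 1)) is continuous and non-decreasing in s with supremum 1,
    so any target in (0, 1) is reachable; solved by bisection.
    """
    w_mean = W.mean()
    lo, hi = 0.0, target / w_mean
    while np.minimum(hi * W, 1.0).mean() < target:
        hi *= 2.0
        if hi > 1e12:
            raise ParameterError("connectance target unreachable after capping")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.minimum(mid * W, 1.0).mean() < target:
            lo = mid
        else:
            hi = mid
    return np.minimum(hi * W, 1.0)


def generate_structured_network(params: StructureParams,
                                max_attempts: int = 50) -> InteractionNetwork:
    """Draw one binary network by independent Bernoulli sampling.

    Deterministic under ``params.seed``; redraws (bounded attempts) if a
    realization comes out all-zero.
    """
    P = _calibrate_probabilities(_rank_weights(params), params.connectance_target)
    rng = np.random.default_rng(params.seed)
    for _ in range(max_attempts):
        B = (rng.random(P.shape) < P).astype(np.int8)
        if B.sum() > 0:
            return InteractionNetwork(id=params.id, incidence=B)
    raise GenerationError(f"{params.id}: no nonzero realization in {max_attempts} attempts")


@dataclass
class SubClassSpec:
    """A planted sub-class: small offsets to the class env mean and ν baseline."""

    name: str
    env_offset: float = 0.0
    nu_offset: float = 0.0


def _default_sub_classes() -> dict[str, list[SubClassSpec]]:
    return {
        MUTUALISTIC: [SubClassSpec("plant-pollinator"), SubClassSpec("seed-dispersal")],
        ANTAGONISTIC: [SubClassSpec("host-parasite"), SubClassSpec("plant-herbivore")],
    }


@dataclass
class ConfoundedSetSpec:
    """Conditions for a confounded two-class community of networks.

    Defaults are the package's reference conditions: 100 networks per
    class; guild sizes uniform in 10–30 with connectance anchored
    inversely to size inside 0.1–0.3 (the empirical size–sparsity
    scaling); temperature variability E ~ Normal(class mean, 2.0 °C) with
    a mild sampling bias (antagonistic mean 0.15 °C higher); nestedness
    ν = ν0_class + b_class·(E − class mean) + Normal(0, 0.15) truncated
    at 0, with opposite coupling slopes b = ±0.6 per °C and a moderate
    baseline offset (mutualistic networks more nested, ν0 2.6 vs 1.85).
    Centering the coupling on the class mean keeps the marginal metric
    distributions strongly overlapping (the baseline offset alone is well
    inside the overlap) while the within-class E–architecture correlation
    has opposite sign across classes — the Simpson structure itself.
    """

    n_per_class: int = 100
    env_mean: dict[str, float] = field(
        default_factory=lambda: {MUTUALISTIC: 4.0, ANTAGONISTIC: 4.15})
    env_sd: dict[str, float] = field(
        default_factory=lambda: {MUTUALISTIC: 2.0, ANTAGONISTIC: 2.0})
    coupling: dict[str, float] = field(
        default_factory=lambda: {MUTUALISTIC: 0.6, ANTAGONISTIC: -0.6})
    nu0: dict[str, float] = field(
        default_factory=lambda: {MUTUALISTIC: 2.6, ANTAGONISTIC: 1.85})
    noise_sd: float = 0.15
    size_connectance_scaling: bool = True  # C decreases with S, as in real webs
    size_range: tuple[int, int] = (10, 30)
    connectance_range: tuple[float, float] = (0.1, 0.3)
    sub_classes: dict[str, list[SubClassSpec]] = field(default_factory=_default_sub_classes)
    env_var: str = DEFAULT_ENV_VAR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ParameterError("n_per_class must be >= 2")
        if any(sd <= 0 for sd in self.env_sd.values()):
            raise ParameterError("env_sd must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        lo, hi = self.size_range
        if lo < 2 or hi < lo:
            raise ParameterError("invalid size_range")

    def without_sampling_bias(self) -> "ConfoundedSetSpec":
        """Same conditions with the class env means pooled (bias off)."""
        pooled = float(np.mean(list(self.env_mean.values())))
        import dataclasses

        return dataclasses.replace(self, env_mean={k: pooled for k in self.env_mean})


def generate_confounded_set(spec: ConfoundedSetSpec) -> NetworkSet:
    """Generate the full two-class community (deterministic under seed)."""
    rng = np.random.default_rng(spec.seed)
    networks = []
    for cls in (MUTUALISTIC, ANTAGONISTIC):
        subs = spec.sub_classes.get(cls) or [SubClassSpec(cls)]
        for i in range(spec.n_per_class):
            sub = subs[int(rng.integers(len(subs)))]
            mean_e = spec.env_mean[cls] + sub.env_offset
            E = float(rng.normal(mean_e, spec.env_sd[cls]))
            nu = max(
                0.0,
                spec.nu0[cls]
                + sub.nu_offset
                + spec.coupling[cls] * (E - mean_e)
                + float(rng.normal(0.0, spec.noise_sd)),
            )
            m = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
            n = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
            c_lo, c_hi = spec.connectance_range
            if spec.size_connectance_scaling:
                # empirical webs are sparser when larger; anchor C to S with jitter
                s_frac = (m + n - 2 * spec.size_range[0]) / (
                    2 * (spec.size_range[1] - spec.size_range[0]))
                C = c_hi - (c_hi - c_lo) * s_frac + float(rng.normal(0.0, 0.02))
                C = float(np.clip(C, c_lo, c_hi))
            else:
                C = float(rng.uniform(c_lo, c_hi))
            params = StructureParams(
                m=m, n=n, connectance_target=C, nu=nu,
                seed=int(rng.integers(2**31 - 1)), id=f"{cls[:3]}_{i:03d}",
            )
            net = generate_structured_network(params)
            net.interaction_class = cls
            net.sub_class = sub.name
            net.env = {spec.env_var: E}
            networks.append(net)
    return NetworkSet(networks, provenance=f"generate_confounded_set(seed={spec.seed})")
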