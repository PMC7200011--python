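"""Stability metrics: λ1, λ2 and the feasibility-domain size Ω.

λ1 and λ2 (from :mod:`envnet.spectral`) index dynamical stability.  Ω
indexes structural stability of the intra-guild competition induced by
shared interaction partners: with incidence B, the overlap Gram matrix
O = B·Bᵀ (row guild) is normalized to unit diagonal,
Â_ij = O_ij/√(O_ii·O_jj), and blended with the identity,
A(ρ) = (1−ρ)·I + ρ·Â, where ρ ∈ [0, 1) sets interspecific competition
strength and guarantees positive definiteness.

Ω is the fraction of the unit sphere of intrinsic growth-rate directions
that admits a feasible (componentwise-positive) equilibrium, i.e. the
solid angle of the cone {A·x : x > 0}.  Writing a uniform direction as
z/‖z‖ with z standard normal, membership is A⁻¹z > 0, so Ω equals the
positive-orthant probability of a centered Gaussian with covariance
Σ = (AᵀA)⁻¹.  The default estimator integrates that orthant probability
with the Genz separation-of-variables transform over scrambled Sobol
points (exact for diagonal A, fast convergence otherwise); a direct
Monte Carlo membership estimator is kept as the independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

from envnet.errors import ParameterError, ValidationError
from envnet.network_io import InteractionNetwork, prune_isolated
from envnet.spectral import leading_eigenvalues

_PD_TOL = 1e-10


@dataclass
class CompetitionSpec:
    """Which guild competes and how strongly (identity blend weight ρ)."""

    guild: str = "rows"  # "rows", "cols" or "both"
    rho: float = 0.5

    def __post_init__(self) -> None:
        if self.guild not in ("rows", "cols", "both"):
            raise ParameterError("guild must be 'rows', 'cols' or 'both'")
        if not 0 <= self.rho <= 1:
            raise ParameterError("rho must be in [0, 1]")


@dataclass
class StabilityMetrics:
    """λ1, λ2 and the Ω estimate for one network/guild."""

    lambda1: float
    lambda2: float
    omega_raw: float
    omega_norm: float  # omega_raw ** (1/S_guild): size-normalized
    S_guild: int
    guild: str
    rho: float
    method: str
    n_draws: int
    seed: int
    stderr: float
    per_guild: dict | None = None  # filled when guild == "both"


def overlap_competition_matrix(incidence, spec: CompetitionSpec) -> np.ndarray:
    """Blended intra-guild competition matrix A = (1−ρ)I + ρÂ.

    Requires a pruned matrix: a zero-degree species in the chosen guild
    gives a zero diagonal in the overlap and no valid normalization.
    ρ = 1 (pure Â) is accepted only when Â is full-rank; a rank-deficient
    Â would give Ω = 0 for any guild larger than its partner guild.
    """
    B = np.asarray(incidence, dtype=float)
    if spec.guild == "cols":
        B = B.T
    elif spec.guild == "both":
        raise ParameterError("build one guild at a time; use stability_bundle for 'both'")
    O = B @ B.T
    d = np.diag(O)
    if (d <= 0).any():
        raise ValidationError("zero-degree species in guild; prune before computing overlap")
    Ahat = O / np.sqrt(np.outer(d, d))
    if spec.rho == 1.0:
        if np.linalg.matrix_rank(Ahat, tol=1e-8) < Ahat.shape[0]:
            raise ParameterError("rho = 1 refused: overlap matrix is rank-deficient")
        return Ahat
    return (1.0 - spec.rho) * np.eye(len(d)) + spec.rho * Ahat


class OmegaEstimate(NamedTuple):
    value: float
    stderr: float


def _check_pd(A: np.ndarray) -> np.ndarray:
    """Validate a cone-defining matrix.

    Symmetric inputs (the competition matrices) must be positive definite;
    general square inputs (e.g. a column-rescaled A·D, which spans the same
    cone) need only be nonsingular.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("A must be square")
    if np.allclose(A, A.T, atol=1e-10):
        try:
            np.linalg.cholesky(A)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("A must be positive definite") from exc
    elif abs(np.linalg.det(A)) < 1e-12:
        raise ValidationError("A must be nonsingular")
    return A


def _genz_orthant_batch(L: np.ndarray, points: np.ndarray) -> float:
    """Genz SOV estimate of P(x > 0), x ~ N(0, LLᵀ), over one point set."""
    N, _ = points.shape
    S = L.shape[0]
    y = np.empty((N, S - 1))
    f = np.full(N, 0.5)  # first factor: P(x_1 > 0) = 0.5
    d = np.full(N, 0.5)
    eps = 1e-15
    for i in range(1, S):
        u = d + points[:, i - 1] * (1.0 - d)
        y[:, i - 1] = ndtri(np.clip(u, eps, 1.0 - eps))
        x = y[:, :i] @ L[i, :i]
        d = ndtr(-x / L[i, i])
        f *= 1.0 - d
    return float(f.mean())


def omega(A, method: str = "orthant", n_draws: int = 20_000,
          seed: int = 0) -> OmegaEstimate:
    """Relative feasibility-domain size of a positive-definite matrix A.

    Parameters
    ----------
    method : {"orthant", "montecarlo"}
        ``orthant``: Genz quasi-Monte Carlo integration of the Gaussian
        positive-orthant probability with covariance (AᵀA)⁻¹ over 10
        independently scrambled Sobol batches (standard error from the
        batch spread).  ``montecarlo``: direct membership counting of
        standard-normal directions — the slow, assumption-free oracle.

    Both are deterministic under ``seed``.  The S = 1 case returns the
    half-line convention Ω = 0.5 with a warning.
    """
    A = _check_pd(A)
    S = A.shape[0]
    if S == 1:
        warnings.warn("omega of a 1x1 matrix: returning the half-line convention 0.5",
                      stacklevel=2)
        return OmegaEstimate(0.5, 0.0)
    if n_draws < 100:
        raise ParameterError("n_draws must be >= 100")
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((n_draws, S))
        Y = np.linalg.solve(A, Z.T).T
        p = float((Y > 0).all(axis=1).mean())
        return OmegaEstimate(p, float(np.sqrt(max(p * (1 - p), 0.0) / n_draws)))
    if method != "orthant":
        raise ValueError(f"unknown method {method!r}")
    Sigma = np.linalg.inv(A.T @ A)
    Sigma = 0.5 * (Sigma + Sigma.T)
    L = np.linalg.cholesky(Sigma)
    n_batches = 10
    m_bits = max(int(np.ceil(np.log2(n_draws / n_batches))), 6)
    ss = np.random.SeedSequence(seed)
    estimates = []
    for child in ss.spawn(n_batches):
        sob = qmc.Sobol(d=S - 1, scramble=True, rng=np.random.default_rng(child))
        pts = sob.random_base2(m_bits)  # power-of-2 sizes keep Sobol balance
        estimates.append(_genz_orthant_batch(L, pts))
    est = np.asarray(estimates)
    return OmegaEstimate(float(est.mean()),
                         float(est.std(ddof=1) / np.sqrt(n_batches)))


def omega_2d_closed_form(A) -> float:
    """Exact Ω for S = 2: the angle between the columns of A over 2π."""
    A = _check_pd(A)
    if A.shape[0] != 2:
        raise ParameterError("closed form is for 2x2 matrices")
    a, b = A[:, 0], A[:, 1]
    c = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.arccos(np.clip(c, -1.0, 1.0)) / (2 * np.pi))


def _one_guild(B, guild: str, rho: float, method: str, n_draws: int, seed: int):
    A = overlap_competition_matrix(B, CompetitionSpec(guild=guild, rho=rho))
    S_guild = A.shape[0]
    est = omega(A, method=method, n_draws=n_draws, seed=seed)
    om_norm = est.value ** (1.0 / S_guild) if est.value > 0 else 0.0
    return est, om_norm, S_guild


def stability_bundle(network: InteractionNetwork, spec: CompetitionSpec | None = None,
                     method: str = "orthant", n_draws: int = 20_000,
                     seed: int = 0) -> StabilityMetrics:
    """All three stability metrics for one network.

    The network is pruned of zero-degree species first.  ``guild="both"``
    reports each guild's Ω in ``per_guild`` with the geometric means as
    the headline values.
    """
    spec = spec or CompetitionSpec()
    net = prune_isolated(network)
    l1, l2 = leading_eigenvalues(net.incidence)
    if spec.guild == "both":
        per = {}
        for g, s in (("rows", seed), ("cols", seed + 1)):
            est, om_norm, S_g = _one_guild(net.incidence, g, spec.rho, method, n_draws, s)
            per[g] = {"omega_raw": est.value, "omega_norm": om_norm,
                      "S_guild": S_g, "stderr": est.stderr}
        raw = float(np.sqrt(per["rows"]["omega_raw"] * per["cols"]["omega_raw"]))
        norm = float(np.sqrt(per["rows"]["omega_norm"] * per["cols"]["omega_norm"]))
        stderr = float(np.hypot(per["rows"]["stderr"], per["cols"]["stderr"]))
        S_guild = per["rows"]["S_guild"] + per["cols"]["S_guild"]
        return StabilityMetrics(l1, l2, raw, norm, S_guild, "both", spec.rho,
                                method, n_draws, seed, stderr, per_guild=per)
    est, om_norm, S_guild = _one_guild(net.incidence, spec.guild, spec.rho,
                                       method, n_draws, seed)
    return StabilityMetrics(l1, l2, est.value, om_norm, S_guild, spec.guild,
                            spec.rho, method, n_draws, seed, est.stderr)
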