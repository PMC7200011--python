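"""Null models for binary bipartite matrices and null-corrected metrics.

Two randomizations are used to correct the spectral metrics for sampling
artefacts of size, connectance and degree:

* ``er`` (Erdős–Rényi): the L links are re-placed uniformly at random among
  the m·n cells, sampling without replacement, so shape and exact link
  count are preserved.  Empty rows/columns may occur and are kept — pruning
  them would break the size-conservation property.
* ``cm`` (configuration): degree-preserving randomization by curveball
  trades; both row and column degree sequences are preserved exactly.
  Each replicate is an independent chain started from the empirical matrix
  and run for ``n_steps`` trades (default 5·L).

The corrected metric is the relative error 1 − mean(λ_null)/λ, i.e. the
fraction of the empirical eigenvalue not explained by the null ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numba import njit

from envnet.errors import GenerationError, UndefinedMetricError, ValidationError
from envnet.network_io import InteractionNetwork
from envnet.spectral import (
    ArchitectureMetrics,
    batched_leading_eigenvalues,
    leading_eigenvalues,
    size_and_connectance,
)

_SEED_MAX = 2**31 - 1


def _as_matrix(x) -> np.ndarray:
    B = x.incidence if isinstance(x, InteractionNetwork) else np.asarray(x)
    if B.ndim != 2 or B.size == 0:
        raise ValidationError("incidence must be a non-empty 2-D matrix")
    if not np.isin(B, (0, 1)).all():
        raise ValidationError("incidence entries must be 0 or 1")
    if B.sum() < 1:
        raise ValidationError("incidence needs at least one link")
    return B.astype(np.int8)


# ---------------------------------------------------------------------------
# Erdős–Rényi null


def er_randomize(incidence, seed: int, require_connected: bool = False,
                 max_attempts: int = 100) -> np.ndarray:
    """One ER replicate: L links placed uniformly among the m·n cells.

    With ``require_connected`` the draw is repeated (bounded attempts)
    until no row or column is empty.
    """
    B = _as_matrix(incidence)
    m, n = B.shape
    L = int(B.sum())
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        out = np.zeros(m * n, dtype=np.int8)
        out[rng.choice(m * n, size=L, replace=False)] = 1
        out = out.reshape(m, n)
        if not require_connected:
            return out
        if (out.sum(axis=1) > 0).all() and (out.sum(axis=0) > 0).all():
            return out
    raise GenerationError("no connected ER replicate within the attempt budget")


def er_ensemble_matrices(incidence, R: int, seed: int) -> np.ndarray:
    """(R, m, n) stack of independent ER replicates (vectorized)."""
    B = _as_matrix(incidence)
    m, n = B.shape
    L = int(B.sum())
    rng = np.random.default_rng(seed)
    keys = rng.random((R, m * n))
    idx = np.argpartition(keys, L - 1, axis=1)[:, :L]
    flat = np.zeros((R, m * n), dtype=np.int8)
    np.put_along_axis(flat, idx, 1, axis=1)
    return flat.reshape(R, m, n)


# ---------------------------------------------------------------------------
# Configuration null (curveball trades)


@njit(cache=False)
def _curveball_trades(M, n_trades, seed):  # pragma: no cover - numba kernel
    np.random.seed(seed)
    m, n = M.shape
    if m < 2:
        return
    pool = np.empty(n, dtype=np.int64)
    for _ in range(n_trades):
        i = np.random.randint(0, m)
        j = np.random.randint(0, m)
        if i == j:
            continue
        ka = 0
        kb = 0
        # columns held by exactly one of the two rows are exchangeable
        for c in range(n):
            a = M[i, c]
            b = M[j, c]
            if a == 1 and b == 0:
                pool[ka] = c
                ka += 1
        for c in range(n):
            if M[i, c] == 0 and M[j, c] == 1:
                pool[ka + kb] = c
                kb += 1
        tot = ka + kb
        if ka == 0 or kb == 0:
            continue
        # Fisher-Yates shuffle of the exchangeable pool
        for t in range(tot - 1, 0, -1):
            u = np.random.randint(0, t + 1)
            tmp = pool[t]
            pool[t] = pool[u]
            pool[u] = tmp
        for t in range(tot):
            c = pool[t]
            if t < ka:
                M[i, c] = 1
                M[j, c] = 0
            else:
                M[i, c] = 0
                M[j, c] = 1


@njit(cache=False)
def _curveball_ensemble(B, R, n_trades, seeds):  # pragma: no cover - numba kernel
    m, n = B.shape
    out = np.empty((R, m, n), dtype=B.dtype)
    for r in range(R):
        M = B.copy()
        _curveball_trades(M, n_trades, seeds[r])
        out[r] = M
    return out


def default_trades(L: int) -> int:
    """Burn-in length for one curveball chain: 5·L trades."""
    return max(1, 5 * int(L))


def cm_randomize(incidence, n_steps: int | None = None, seed: int = 0) -> np.ndarray:
    """One configuration-model replicate with exact degree preservation.

    Matrices whose margins admit a unique realization come back unchanged
    (no trade is ever possible).
    """
    B = _as_matrix(incidence)
    if n_steps is None:
        n_steps = default_trades(B.sum())
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    M = B.copy()
    _curveball_trades(M, n_steps, int(seed) % _SEED_MAX)
    return M


def cm_ensemble_matrices(incidence, R: int, seed: int,
                         n_steps: int | None = None) -> np.ndarray:
    """(R, m, n) stack of independent curveball chains."""
    B = _as_matrix(incidence)
    if n_steps is None:
        n_steps = default_trades(B.sum())
    seeds = np.random.default_rng(seed).integers(0, _SEED_MAX, size=R)
    return _curveball_ensemble(B, R, n_steps, seeds)


# ---------------------------------------------------------------------------
# Ensembles and relative errors


@dataclass
class NullEnsemble:
    """Spectral metrics of R randomized replicates of one matrix."""

    model: str  # "er" or "cm"
    replicate_metrics: np.ndarray  # (R, 2): lambda1, lambda2 per replicate
    R: int
    seed: int

    def mean(self, which: int) -> float:
        return float(self.replicate_metrics[:, which].mean())

    def sd(self, which: int) -> float:
        return float(self.replicate_metrics[:, which].std(ddof=1))


def build_null_ensemble(incidence, model: str, R: int, seed: int,
                        n_steps: int | None = None) -> NullEnsemble:
    if R < 1:
        raise ValidationError("R must be >= 1")
    if model == "er":
        stack = er_ensemble_matrices(incidence, R, seed)
    elif model == "cm":
        stack = cm_ensemble_matrices(incidence, R, seed, n_steps=n_steps)
    else:
        raise ValueError(f"unknown null model {model!r}")
    return NullEnsemble(model=model, replicate_metrics=batched_leading_eigenvalues(stack),
                        R=R, seed=seed)


class RelativeError(NamedTuple):
    """Null-corrected relative error with its ensemble statistics."""

    value: float
    null_mean: float
    null_sd: float


def relative_error(empirical: float, null_values) -> RelativeError:
    """1 − mean(null)/empirical, with the null standard deviation.

    Negative values are legal (the null ensemble can exceed the empirical
    value).  ``empirical <= 0`` (λ2 of a rank-1 matrix) raises
    :class:`UndefinedMetricError`; callers propagate it as a missing value.
    """
    vals = np.asarray(null_values, dtype=float)
    if vals.size == 0:
        raise ValidationError("null_values must be non-empty")
    if empirical <= 0:
        raise UndefinedMetricError("relative error undefined for empirical value <= 0")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return RelativeError(1.0 - float(vals.mean()) / empirical, float(vals.mean()), sd)


_L2_TOL = 1e-10


def null_corrected_metrics(network, R: int = 100, seed: int = 0,
                           n_steps: int | None = None) -> ArchitectureMetrics:
    """Fill the three null-corrected relative errors for one network.

    Builds one ER and one configuration ensemble (R replicates each,
    deterministic under ``seed``) and returns the full metrics bundle:
    1−λ1^cm/λ1, 1−λ1^er/λ1 and 1−λ2^er/λ2.  When λ2 is numerically zero
    the λ2 relative error is undefined and reported as NaN with a warning;
    downstream feature assembly excludes such networks.
    """
    if R < 2:
        raise ValidationError("R must be >= 2")
    B = _as_matrix(network)
    l1, l2 = leading_eigenvalues(B)
    S, C = size_and_connectance(B)
    rng = np.random.default_rng(seed)
    seed_er, seed_cm = (int(s) for s in rng.integers(0, _SEED_MAX, size=2))
    ens_er = build_null_ensemble(B, "er", R, seed_er)
    ens_cm = build_null_ensemble(B, "cm", R, seed_cm, n_steps=n_steps)
    rel_l1_cm = relative_error(l1, ens_cm.replicate_metrics[:, 0]).value
    rel_l1_er = relative_error(l1, ens_er.replicate_metrics[:, 0]).value
    if l2 <= _L2_TOL:
        nid = network.id if isinstance(network, InteractionNetwork) else "<matrix>"
        warnings.warn(f"{nid}: λ2 is zero; λ2 relative error undefined", stacklevel=2)
        rel_l2_er = np.nan
    else:
        rel_l2_er = relative_error(l2, ens_er.replicate_metrics[:, 1]).value
    return ArchitectureMetrics(
        lambda1=l1, lambda2=l2, size_S=S, connectance_C=C,
        rel_err_l1_cm=rel_l1_cm, rel_err_l1_er=rel_l1_er, rel_err_l2_er=rel_l2_er,
    )
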