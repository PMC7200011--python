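"""Spectral architecture metrics of binary bipartite networks.

The architecture of a bipartite network with incidence matrix B is
summarised by the two largest eigenvalues of the symmetric bipartite
adjacency ``[[0, B], [Bᵀ, 0]]``.  The positive spectrum of that matrix is
exactly the singular-value spectrum of B, so λ1 = σ1(B) and λ2 = σ2(B);
computing singular values keeps the result real, non-negative and
numerically symmetric-safe.  λ1 rises with nestedness (its upper bound is
attained by perfectly nested matrices at fixed size and fill), λ2 with
modularity (a second dense block contributes a second large singular
value).  Size S = m + n and connectance C = L/(m·n) complete the raw
description; the null-corrected relative errors are filled by
:mod:`envnet.null_models`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from envnet.errors import ValidationError


@dataclass
class ArchitectureMetrics:
    """Raw spectral metrics plus null-corrected relative errors.

    ``rel_err_*`` fields are ``1 − mean(λ_null)/λ`` for the configuration
    (cm) and Erdős–Rényi (er) null models; they are NaN until filled by
    :func:`envnet.null_models.null_corrected_metrics`.
    """

    lambda1: float
    lambda2: float
    size_S: int
    connectance_C: float
    rel_err_l1_cm: float = np.nan
    rel_err_l1_er: float = np.nan
    rel_err_l2_er: float = np.nan

    def __post_init__(self) -> None:
        if self.lambda1 < self.lambda2 - 1e-12:
            raise ValidationError("lambda1 must be >= lambda2")


def _validate(incidence) -> np.ndarray:
    B = np.asarray(incidence)
    if B.ndim != 2 or B.size == 0:
        raise ValidationError("incidence must be a non-empty 2-D matrix")
    if B.sum() == 0:
        raise ValidationError("incidence has no interactions")
    return B.astype(float)


def leading_eigenvalues(incidence) -> tuple[float, float]:
    """Two largest eigenvalues of the bipartite adjacency of ``incidence``.

    Equals the two largest singular values of B; λ2 = 0 whenever
    rank(B) = 1 (e.g. a fully connected matrix).
    """
    B = _validate(incidence)
    s = np.linalg.svd(B, compute_uv=False)
    l1 = float(s[0])
    l2 = float(s[1]) if s.size > 1 else 0.0
    return l1, l2


def batched_leading_eigenvalues(stack: np.ndarray) -> np.ndarray:
    """Top-2 singular values for a (R, m, n) stack of matrices.

    Returns an (R, 2) array; used for null-model ensembles where the
    per-call overhead of :func:`leading_eigenvalues` would dominate.
    """
    s = np.linalg.svd(np.asarray(stack, dtype=float), compute_uv=False)
    out = np.zeros((s.shape[0], 2))
    out[:, 0] = s[:, 0]
    if s.shape[1] > 1:
        out[:, 1] = s[:, 1]
    return out


def size_and_connectance(incidence) -> tuple[int, float]:
    """Network size S = m + n and connectance C = links / (m·n)."""
    B = np.asarray(incidence)
    if B.ndim != 2 or B.size == 0:
        raise ValidationError("incidence must be a non-empty 2-D matrix")
    m, n = B.shape
    return m + n, float(B.sum()) / (m * n)


def architecture_metrics(incidence) -> ArchitectureMetrics:
    """Raw metrics bundle (relative errors left NaN)."""
    l1, l2 = leading_eigenvalues(incidence)
    S, C = size_and_connectance(incidence)
    return ArchitectureMetrics(lambda1=l1, lambda2=l2, size_S=S, connectance_C=C)
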