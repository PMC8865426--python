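"""Normalized-Laplacian spectral clustering of a single similarity layer.

Used for per-data-type clustering and comparisons against the integrative
solution. The number of clusters, when not given, is chosen by the largest
consecutive eigenvalue gap of the normalized Laplacian (ascending spectrum),
excluding the trivial connectivity gap between the zero-th and first
eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .simnet import SimilarityLayer

logger = logging.getLogger(__name__)

__all__ = ["SpectralResult", "spectral_cluster"]

#: gaps below this are treated as flat spectrum (single cluster)
_GAP_TOL = 1e-10


@dataclass
class SpectralResult:
    labels: np.ndarray
    chosen_k: int
    eigenvalues: np.ndarray  # normalized-Laplacian spectrum, ascending


def _as_matrix(A) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(A, SimilarityLayer):
        M = np.where(A.W > 0, np.nan_to_num(A.A), np.nan)
        return M, None
    return np.asarray(A, dtype=float), None


def spectral_cluster(
    A,
    k: int | None = None,
    max_k: int = 10,
    seed: int = 0,
) -> SpectralResult:
    """Cluster one similarity matrix (or :class:`SimilarityLayer`).

    Unavailable entries are treated as 0 with a warning. The normalized
    Laplacian is ``L = I - D^{-1/2} A D^{-1/2}``; when ``k`` is not given it
    is set to the index of the largest consecutive eigenvalue gap among the
    first ``max_k`` eigenvalues (k >= 2; a flat tail selects k = 1). The
    first k eigenvectors are row-normalized and clustered with k-means.
    Labels are invariant to positive rescaling of A.
    """
    M, _ = _as_matrix(A)
    if M.shape[0] != M.shape[1]:
        raise ValueError("similarity matrix must be square")
    n = M.shape[0]
    if np.isnan(M).any():
        logger.warning("unavailable similarity entries treated as 0")
        M = np.nan_to_num(M)
    if (M < -1e-12).any():
        raise ValueError("similarity matrix must be nonnegative")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    d = M.sum(axis=1)
    dead = np.flatnonzero(d <= 0)
    if dead.size:
        raise ValueError(f"isolated sample(s) with zero degree: index {dead[0]}")
    dinv = 1.0 / np.sqrt(d)
    L = np.eye(n) - dinv[:, None] * M * dinv[None, :]
    L = (L + L.T) / 2.0
    evals, evecs = np.linalg.eigh(L)
    evals = np.clip(evals, 0.0, 2.0)
    if k is None:
        top = min(max_k, n - 1)
        # gap g_k = lambda_k - lambda_{k-1} measured for k = 2..top;
        # the 0->1 gap only detects connectivity and is excluded
        gaps = evals[2 : top + 1] - evals[1:top]
        if gaps.size == 0 or gaps.max() < _GAP_TOL:
            k = 1
        else:
            k = int(np.argmax(gaps)) + 2
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return SpectralResult(np.zeros(n, dtype=int), 1, evals)
    emb = evecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    labels = km.fit_predict(emb)
    return SpectralResult(labels, k, evals)
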