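"""Construction of the multiplex patient-similarity network.

Each preprocessed layer is turned into a symmetric n x n similarity matrix
``A`` with entries in [0, 1] plus a binary availability mask ``W``. The
default kernel is a locally scaled RBF of the Euclidean distance; cosine,
Pearson and Spearman similarities are available as alternatives.

Missing data are handled without imputation: the pairwise distance between
two samples is computed over their common observed features and inflated by
``p / |common|``; pairs with insufficient overlap (below a fraction of the
feature count, default 10%) are marked unavailable (``W = 0``) and excluded
from all downstream computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityLayer",
    "MultiplexNetwork",
    "NetworkConfig",
    "pairwise_distance",
    "default_num_neighbors",
    "local_scale",
    "rbf_similarity",
    "correlation_similarity",
    "build_network",
]

METRICS = ("euclidean-rbf", "cosine", "pearson", "spearman")


@dataclass
class SimilarityLayer:
    """Symmetric similarity matrix with availability mask for one data type.

    Attributes
    ----------
    A : ndarray of shape (n, n)
        Similarities in [0, 1]; entries where ``W == 0`` are NaN.
    W : ndarray of shape (n, n)
        Binary availability mask; ``W[i, j] = 0`` when the overlap rule fails
        or a sample is absent from the layer.
    n_layer : int
        Number of roster samples with any data in this layer.
    lambda_weight : float
        Per-layer objective weight, ``n_layer ** -2``.
    """

    A: np.ndarray
    W: np.ndarray
    n_layer: int
    lambda_weight: float
    metric: str = "euclidean-rbf"
    name: str = "layer"

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def masked(self) -> np.ndarray:
        """A with unavailable entries replaced by 0 (W o A)."""
        return np.where(self.W > 0, np.nan_to_num(self.A), 0.0)

    def validate(self) -> None:
        A, W = self.A, self.W
        if A.shape != W.shape or A.shape[0] != A.shape[1]:
            raise ValueError("A and W must be square and congruent")
        if not np.array_equal(W, W.T):
            raise ValueError("W is not symmetric")
        avail = W > 0
        if not np.allclose(
            np.where(avail, np.nan_to_num(A), 0.0),
            np.where(avail, np.nan_to_num(A), 0.0).T,
            atol=1e-12,
        ):
            raise ValueError("A is not symmetric on available entries")
        vals = A[avail]
        if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise ValueError("available similarities outside [0, 1]")


@dataclass
class MultiplexNetwork:
    """Ordered set of similarity layers over a shared sample roster."""

    layers: list[SimilarityLayer]
    sample_ids: list[str]

    @property
    def t(self) -> int:
        return len(self.layers)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        n = self.n
        for lay in self.layers:
            if lay.n != n:
                raise ValueError("layer size does not match roster")
            lay.validate()
        present = np.zeros(n, dtype=bool)
        for lay in self.layers:
            present |= np.diag(lay.W) > 0
        if not present.all():
            missing = [s for s, ok in zip(self.sample_ids, present) if not ok]
            raise ValueError(f"samples with no data in any layer: {missing[:5]}")

    def subset(self, idx: np.ndarray) -> "MultiplexNetwork":
        """Row/column-subset network (used by resampled consensus runs)."""
        idx = np.asarray(idx)
        layers = []
        for lay in self.layers:
            A = lay.A[np.ix_(idx, idx)]
            W = lay.W[np.ix_(idx, idx)]
            n_layer = int((np.diag(W) > 0).sum())
            lam = 1.0 / n_layer**2 if n_layer else 0.0
            layers.append(
                SimilarityLayer(A, W, n_layer, lam, lay.metric, lay.name)
            )
        return MultiplexNetwork(layers, [self.sample_ids[i] for i in idx])


@dataclass
class NetworkConfig:
    """Hyperparameters for similarity construction."""

    metrics: list[str] = field(default_factory=list)  # per layer; default RBF
    mu: float = 0.5
    k_fraction: float = 0.1
    min_overlap_fraction: float = 0.1


def pairwise_distance(
    m: FeatureMatrix, min_overlap_fraction: float = 0.1
) -> np.ndarray:
    """Overlap-scaled Euclidean distance matrix with unavailable entries.

    For samples i, j with common observed feature set C:
    ``rho^2 = (p / |C|) * sum_{f in C} (x_if - x_jf)^2``. Entries with
    ``|C| < min_overlap_fraction * p`` are NaN (unavailable). Returns the
    distance rho (not squared); the diagonal is 0 for samples with any data.
    With complete data this reduces to the plain Euclidean distance.
    """
    X = m.values
    n, p = X.shape
    obs = np.isfinite(X)
    empty = ~obs.any(axis=1)
    if empty.any():
        logger.warning(
            "layer %s: %d sample(s) with zero observed features",
            m.layer_name,
            int(empty.sum()),
        )
    X0 = np.where(obs, X, 0.0)
    O = obs.astype(float)
    common = O @ O.T  # |C_ij|
    sq_i = (X0**2) @ O.T  # sum over common of x_i^2
    cross = X0 @ X0.T
    sq = sq_i + sq_i.T - 2.0 * cross
    np.maximum(sq, 0.0, out=sq)
    min_common = min_overlap_fraction * p
    with np.errstate(divide="ignore", invalid="ignore"):
        rho2 = np.where(common > 0, p / np.maximum(common, 1) * sq, np.nan)
    rho2[common < min_common] = np.nan
    D = np.sqrt(rho2)
    # diagonal: 0 where the sample has data at all
    di = np.arange(n)
    D[di, di] = np.where(empty, np.nan, 0.0)
    return D


def default_num_neighbors(n_available: int, k_fraction: float = 0.1) -> int:
    """Default neighborhood size: ``max(1, round(k_fraction * n))``."""
    return max(1, int(round(k_fraction * n_available)))


def local_scale(D: np.ndarray, K: int) -> np.ndarray:
    """Per-sample kernel bandwidth: mean distance to the K nearest neighbors.

    Unavailable and diagonal entries are excluded. Samples with fewer than K
    available neighbors fall back to the mean over all available neighbors
    (with a warning); samples with none get a NaN scale.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = D.shape[0]
    eps = np.full(n, np.nan)
    short = 0
    for i in range(n):
        row = D[i].copy()
        row[i] = np.nan
        avail = row[np.isfinite(row)]
        if avail.size == 0:
            continue
        if avail.size < K:
            short += 1
            eps[i] = avail.mean()
        else:
            eps[i] = np.sort(avail)[:K].mean()
    if short:
        logger.warning(
            "%d sample(s) had fewer than K=%d available neighbors; "
            "used all available",
            short,
            K,
        )
    return eps


def rbf_similarity(
    D: np.ndarray,
    eps: np.ndarray,
    mu: float = 0.5,
    metric_name: str = "euclidean-rbf",
    layer_name: str = "layer",
) -> SimilarityLayer:
    """Locally scaled RBF similarity: ``A_ij = exp(-rho^2 / (mu eps_i eps_j))``.

    The diagonal is forced to 1 for present samples. A zero local scale
    (duplicate points) gives similarity 1 at rho = 0 and 0 otherwise, by the
    continuity convention.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    n = D.shape[0]
    denom = mu * np.outer(eps, eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.exp(-(D**2) / denom)
        # eps == 0 -> denom 0: exp(-inf) for rho>0 handled below
        zero_denom = denom == 0
        if zero_denom.any():
            A[zero_denom & (D > 0)] = 0.0
            A[zero_denom & (D == 0)] = 1.0
    avail = np.isfinite(D) & np.isfinite(A)
    di = np.arange(n)
    present = np.isfinite(D[di, di])
    A[di, di] = np.where(present, 1.0, np.nan)
    avail[di, di] = present
    W = avail.astype(float)
    A[~avail] = np.nan
    n_layer = int(present.sum())
    lam = 1.0 / n_layer**2 if n_layer else 0.0
    return SimilarityLayer(A, W, n_layer, lam, metric_name, layer_name)


def _pairwise_corr(
    X: np.ndarray, metric: str, min_overlap_fraction: float
) -> np.ndarray:
    """Raw correlation/cosine matrix in [-1, 1] with NaN where unavailable."""
    n, p = X.shape
    obs = np.isfinite(X)
    complete = obs.all()
    if metric == "spearman" and complete:
        X = np.apply_along_axis(rankdata, 1, X)
        metric = "pearson"
    if complete:
        if metric == "cosine":
            norms = np.linalg.norm(X, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                R = (X @ X.T) / np.outer(norms, norms)
            R[~np.isfinite(R)] = np.nan
        else:  # pearson
            sd = X.std(axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                R = np.corrcoef(X)
            R[sd == 0, :] = np.nan
            R[:, sd == 0] = np.nan
        return np.clip(R, -1.0, 1.0)
    # missing-data path: per-pair computation over common features
    min_common = max(2.0, min_overlap_fraction * p)
    R = np.full((n, n), np.nan)
    for i in range(n):
        R[i, i] = 1.0 if obs[i].any() else np.nan
        for j in range(i + 1, n):
            c = obs[i] & obs[j]
            if c.sum() < min_common:
                continue
            x, y = X[i, c], X[j, c]
            if metric == "spearman":
                x, y = rankdata(x), rankdata(y)
            if metric == "cosine":
                nx, ny = np.linalg.norm(x), np.linalg.norm(y)
                if nx == 0 or ny == 0:
                    continue
                r = float(x @ y / (nx * ny))
            else:
                if x.std() == 0 or y.std() == 0:
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
            R[i, j] = R[j, i] = min(1.0, max(-1.0, r))
    return R


def correlation_similarity(
    m: FeatureMatrix, metric: str, min_overlap_fraction: float = 0.1
) -> SimilarityLayer:
    """Cosine/Pearson/Spearman similarity mapped affinely into [0, 1].

    The raw score r in [-1, 1] becomes ``(1 + r) / 2``, preserving ordering;
    zero-variance vectors (under pearson/spearman) and pairs failing the
    overlap rule are unavailable.
    """
    if metric not in ("cosine", "pearson", "spearman"):
        raise ValueError(f"unknown correlation metric {metric!r}")
    R = _pairwise_corr(m.values, metric, min_overlap_fraction)
    A = (1.0 + R) / 2.0
    n = A.shape[0]
    di = np.arange(n)
    present = np.isfinite(m.values).any(axis=1)
    A[di, di] = np.where(present, 1.0, np.nan)
    avail = np.isfinite(A)
    W = avail.astype(float)
    n_layer = int(present.sum())
    lam = 1.0 / n_layer**2 if n_layer else 0.0
    return SimilarityLayer(A, W, n_layer, lam, metric, m.layer_name)


def build_network(
    layers: list[FeatureMatrix], config: NetworkConfig | None = None
) -> MultiplexNetwork:
    """Assemble the multiplex network from preprocessed feature matrices.

    The roster is the union of sample ids (in order of first appearance);
    samples absent from a layer get all-zero mask rows/columns in it. Each
    layer carries its own weight ``lambda = n_layer ** -2``.
    """
    if config is None:
        config = NetworkConfig()
    if not layers:
        raise ValueError("at least one layer is required")
    roster: list[str] = []
    seen = set()
    for m in layers:
        if len(set(m.sample_ids)) != len(m.sample_ids):
            raise ValueError(f"duplicate sample ids in layer {m.layer_name}")
        for s in m.sample_ids:
            if s not in seen:
                seen.add(s)
                roster.append(s)
    metrics = config.metrics or ["euclidean-rbf"] * len(layers)
    if len(metrics) == 1 and len(layers) > 1:
        metrics = metrics * len(layers)
    if len(metrics) != len(layers):
        raise ValueError("one metric per layer required")
    sim_layers = []
    for m, metric in zip(layers, metrics):
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        aligned = _align(m, roster)
        if metric == "euclidean-rbf":
            D = pairwise_distance(aligned, config.min_overlap_fraction)
            n_avail = int(np.isfinite(np.diag(D)).sum())
            K = default_num_neighbors(n_avail, config.k_fraction)
            eps = local_scale(D, K)
            lay = rbf_similarity(D, eps, config.mu, metric, m.layer_name)
        else:
            lay = correlation_similarity(aligned, metric, config.min_overlap_fraction)
        sim_layers.append(lay)
    net = MultiplexNetwork(sim_layers, roster)
    net.validate()
    return net


def _align(m: FeatureMatrix, roster: list[str]) -> FeatureMatrix:
    """Reindex a layer onto the full roster, NaN rows for absent samples."""
    if m.sample_ids == roster:
        return m
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    out = np.full((len(roster), m.n_features), np.nan)
    for i, s in enumerate(roster):
        j = pos.get(s)
        if j is not None:
            out[i] = m.values[j]
    return FeatureMatrix(out, roster, m.feature_ids, m.layer_name)
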