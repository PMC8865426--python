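"""Resampled consensus clustering over tri-factorization runs.

The solver is run many times (default 60) on random 95% subsets of the
samples with randomly perturbed core initializations. Run-wise co-clustering
indicators are averaged into a consensus matrix with weights derived from
each run's residual error; final labels come from Normalized-Cut clustering
of that matrix. PAC and CCC over consensus matrices built from random run
subsets quantify stability and drive the choice of the number of clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .factorize import SolverConfig, factorize, hard_labels, svd_init
from .simnet import MultiplexNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "RunRecord",
    "RunEnsemble",
    "ConsensusResult",
    "run_resampled",
    "weighted_consensus",
    "ncut_labels",
    "pac",
    "ccc",
    "cluster_network",
    "select_rank",
    "select_eta",
    "RankSelection",
]

PAC_LOWER, PAC_UPPER = 0.1, 0.9
PAC_RECOMMEND = 0.1
CCC_RECOMMEND = 0.95


@dataclass
class RunRecord:
    """One resampled solver run: sampled indices, their labels, residual error."""

    indices: np.ndarray
    labels: np.ndarray
    RE: float


@dataclass
class RunEnsemble:
    runs: list[RunRecord]
    n: int
    r: int
    keep_fraction: float

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass
class ConsensusResult:
    C: np.ndarray
    labels: np.ndarray
    rank: int
    pac: float
    ccc: float
    pac_dist: list[float] = field(default_factory=list)
    ccc_dist: list[float] = field(default_factory=list)


def run_resampled(
    network: MultiplexNetwork,
    config: SolverConfig,
    n_runs: int = 60,
    keep_fraction: float = 0.95,
    seed: int = 0,
) -> RunEnsemble:
    """Solve on ``n_runs`` random sample subsets with perturbed initializations.

    Each run keeps ``floor(keep_fraction * n)`` samples. H is initialized
    deterministically from the subset's SVD; the diagonal core initialization
    is scaled by fresh uniform factors in [0.5, 1.5] so runs differ even on
    identical subsets. Any sample never drawn is forced into the last runs so
    every sample is clustered at least once.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    n = network.n
    n_keep = max(config.r, int(np.floor(keep_fraction * n)))
    rng = np.random.default_rng(seed)
    subsets = [
        np.sort(rng.choice(n, size=n_keep, replace=False)) for _ in range(n_runs)
    ]
    covered = np.zeros(n, dtype=bool)
    for s in subsets:
        covered[s] = True
    uncovered = np.flatnonzero(~covered)
    for pos, u in enumerate(uncovered):
        x = n_runs - 1 - (pos % n_runs)
        s = subsets[x]
        # replace a random member that is covered elsewhere
        replaceable = [i for i in range(len(s)) if s[i] not in uncovered]
        drop = replaceable[rng.integers(len(replaceable))]
        s[drop] = u
        subsets[x] = np.sort(s)

    runs = []
    for x in range(n_runs):
        sub = network.subset(subsets[x])
        H0, S0_list = svd_init(sub, config.r)
        S0_list = [S * rng.uniform(0.5, 1.5, size=S.shape[0]) for S in S0_list]
        res = factorize(sub, config, init=(H0, S0_list))
        runs.append(RunRecord(subsets[x], hard_labels(res.H), res.RE))
    return RunEnsemble(runs, n, config.r, keep_fraction)


def weighted_consensus(
    ensemble: RunEnsemble, run_subset: list[int] | None = None
) -> np.ndarray:
    """Residual-error-weighted consensus matrix.

    ``weight(x) = (M - RE(x)) / (M - N)`` with M/N the max/min RE over the
    selected runs (all weights 1 when M == N). Each pair's consensus is the
    weight-normalized average of its co-clustering indicator over the runs
    where both samples were sampled; pairs never co-sampled under positive
    weight are set to 0 with a warning.
    """
    runs = ensemble.runs
    if run_subset is not None:
        runs = [runs[i] for i in run_subset]
    if not runs:
        raise ValueError("empty ensemble")
    n = ensemble.n
    res = np.array([r.RE for r in runs])
    M, N = res.max(), res.min()
    if M == N:
        weights = np.ones(len(runs))
    else:
        weights = (M - res) / (M - N)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for rec, w in zip(runs, weights):
        idx = rec.indices
        co = (rec.labels[:, None] == rec.labels[None, :]).astype(float)
        num[np.ix_(idx, idx)] += w * co
        den[np.ix_(idx, idx)] += w
    undefined = den == 0
    if undefined.any():
        n_undef = int(undefined.sum() - np.diag(undefined).sum())
        if n_undef:
            logger.warning(
                "%d consensus pair(s) never co-sampled under positive weight; "
                "set to 0",
                n_undef // 2,
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(undefined, 0.0, num / np.maximum(den, 1e-300))
    np.fill_diagonal(C, 1.0)
    return C


def ncut_labels(C: np.ndarray, r: int, seed: int = 0) -> np.ndarray:
    """Normalized-Cut partition of a consensus matrix into r groups.

    Spectral embedding with the symmetric normalized Laplacian of C followed
    by k-means (multiple restarts, fixed seed) on the row-normalized leading
    eigenvectors.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    n = C.shape[0]
    if r == 1:
        return np.zeros(n, dtype=int)
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("consensus matrix must be symmetric")
    d = C.sum(axis=1)
    if (d <= 0).any():
        logger.warning("isolated sample(s) in consensus matrix; degrees floored")
        d = np.maximum(d, 1e-12)
    dinv = 1.0 / np.sqrt(d)
    M = dinv[:, None] * C * dinv[None, :]
    M = (M + M.T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    # largest eigenvalues of D^-1/2 C D^-1/2 == smallest of I - it
    n_comp = int((evals > 1.0 - 1e-9).sum())
    if n_comp > r:
        logger.warning(
            "consensus graph has ~%d components for r=%d; best-effort labels",
            n_comp,
            r,
        )
    emb = evecs[:, -r:]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=r, n_init=20, random_state=seed)
    return km.fit_predict(emb)


def pac(C: np.ndarray) -> float:
    """Proportion of ambiguous pairs: off-diagonal upper-triangle consensus
    entries strictly inside (0.1, 0.9). Lower is more stable."""
    n = C.shape[0]
    if n < 2:
        raise ValueError("PAC needs at least 2 samples")
    iu = np.triu_indices(n, k=1)
    v = C[iu]
    return float(np.mean((v > PAC_LOWER) & (v < PAC_UPPER)))


def ccc(C: np.ndarray) -> float:
    """Cophenetic correlation of the consensus dissimilarity 1 - C.

    Average-linkage hierarchical clustering of 1 - C; CCC is the Pearson
    correlation between cophenetic distances and the original dissimilarities
    over all pairs. Returns NaN when the dissimilarity is constant.
    """
    n = C.shape[0]
    if n < 3:
        raise ValueError("CCC needs at least 3 samples")
    D = 1.0 - np.asarray(C, dtype=float)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    np.maximum(D, 0.0, out=D)
    dvec = squareform(D, checks=False)
    if np.allclose(dvec, dvec[0]):
        return float("nan")
    Z = linkage(dvec, method="average")
    coef, _ = cophenet(Z, dvec)
    return float(coef)


def cluster_network(
    network: MultiplexNetwork,
    r: int,
    config: SolverConfig | None = None,
    n_runs: int = 60,
    keep_fraction: float = 0.95,
    subset_size: int | None = 50,
    n_subsets: int = 10,
    seed: int = 0,
) -> ConsensusResult:
    """Full consensus pipeline at one rank.

    Labels come from the consensus matrix over *all* runs; PAC/CCC
    distributions come from consensus matrices over ``n_subsets`` random run
    subsets of size ``subset_size`` (clipped to the ensemble size).
    """
    if config is None:
        config = SolverConfig(r=r)
    else:
        config = SolverConfig(
            r=r, eta=config.eta, tol=config.tol, max_iter=config.max_iter,
            seed=config.seed,
        )
    ens = run_resampled(network, config, n_runs, keep_fraction, seed=seed)
    C = weighted_consensus(ens)
    labels = ncut_labels(C, r, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, r, 0x5EED]))
    pac_dist, ccc_dist = [], []
    size = min(subset_size or n_runs, ens.n_runs)
    for _ in range(n_subsets):
        pick = sorted(rng.choice(ens.n_runs, size=size, replace=False).tolist())
        Cs = weighted_consensus(ens, run_subset=pick)
        pac_dist.append(pac(Cs))
        ccc_dist.append(ccc(Cs))
    found = len(np.unique(labels))
    if found < r:
        logger.info("rank %d produced only %d nonempty clusters", r, found)
    return ConsensusResult(
        C=C,
        labels=labels,
        rank=r,
        pac=pac(C),
        ccc=ccc(C),
        pac_dist=pac_dist,
        ccc_dist=ccc_dist,
    )


@dataclass
class RankSelection:
    table: pd.DataFrame
    results: dict[int, ConsensusResult]
    recommended: list[int]


def select_rank(
    network: MultiplexNetwork,
    rank_range,
    config: SolverConfig | None = None,
    n_runs: int = 60,
    keep_fraction: float = 0.95,
    subset_size: int = 50,
    n_subsets: int = 10,
    seed: int = 0,
) -> RankSelection:
    """Stability report over candidate ranks.

    For each rank the consensus pipeline is run; ranks whose median PAC over
    the run-subset consensus matrices is below 0.1 and median CCC above 0.95
    are recommended (reported, not auto-chosen).
    """
    ranks = [int(r) for r in rank_range]
    if not ranks:
        raise ValueError("rank_range is empty")
    rows = []
    results: dict[int, ConsensusResult] = {}
    for r in ranks:
        if r >= network.n:
            logger.warning("rank %d >= n=%d; skipped", r, network.n)
            continue
        res = cluster_network(
            network,
            r,
            config,
            n_runs=n_runs,
            keep_fraction=keep_fraction,
            subset_size=subset_size,
            n_subsets=n_subsets,
            seed=seed + r,
        )
        results[r] = res
        med_pac = float(np.median(res.pac_dist))
        with np.errstate(invalid="ignore"):
            med_ccc = float(np.nanmedian(res.ccc_dist))
        rows.append(
            {
                "rank": r,
                "median_pac": med_pac,
                "median_ccc": med_ccc,
                "pac_all_runs": res.pac,
                "ccc_all_runs": res.ccc,
                "recommended": bool(
                    med_pac < PAC_RECOMMEND and med_ccc > CCC_RECOMMEND
                ),
            }
        )
    if not rows:
        raise ValueError("no usable rank in rank_range")
    table = pd.DataFrame(rows)
    recommended = [int(r) for r in table.loc[table["recommended"], "rank"]]
    return RankSelection(table, results, recommended)


def within_cluster_similarity_score(
    network: MultiplexNetwork, labels: np.ndarray
) -> float:
    """Sparsity-selection score: ``s = sum_j sum_i sim(C_i, A_j) / n_j^2``
    where ``sim`` sums available similarities over within-cluster pairs."""
    labels = np.asarray(labels)
    score = 0.0
    for lay in network.layers:
        if lay.n_layer == 0:
            continue
        WA = lay.masked()
        layer_sum = 0.0
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            block = WA[np.ix_(idx, idx)]
            # unordered within-cluster pairs (diagonal excluded)
            layer_sum += (block.sum() - np.trace(block)) / 2.0
        score += layer_sum / lay.n_layer**2
    return float(score)


def select_eta(
    network: MultiplexNetwork,
    eta_candidates,
    r: int,
    config: SolverConfig | None = None,
    n_runs: int = 20,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick the sparsity weight maximizing within-cluster similarity.

    Ties go to the smaller candidate. The default candidate grid used by the
    CLI includes 0.1.
    """
    cands = sorted(float(e) for e in eta_candidates)
    if not cands:
        raise ValueError("eta_candidates is empty")
    rows = []
    best_eta, best_score = None, -np.inf
    for eta in cands:
        cfg = SolverConfig(
            r=r,
            eta=eta,
            tol=(config.tol if config else 1e-7),
            max_iter=(config.max_iter if config else 500),
        )
        res = cluster_network(
            network, r, cfg, n_runs=n_runs, n_subsets=0, seed=seed
        )
        s = within_cluster_similarity_score(network, res.labels)
        rows.append({"eta": eta, "score": s})
        if s > best_score:  # strict: ties keep the smaller (earlier) eta
            best_eta, best_score = eta, s
    return float(best_eta), pd.DataFrame(rows)
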