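"""Synthetic multi-layer cohorts with known ground truth.

Cohorts are isotropic Gaussian blobs around well-separated centers; noise and
layer-level missing samples can then be layered on. Every generator is a pure
function of its arguments (same seed -> bit-identical output), which makes the
downstream pipeline testable end to end without external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohort",
    "make_blobs",
    "replicate_layer",
    "add_noise",
    "drop_samples",
    "noise_sweep_experiment",
    "default_pipeline_method",
]

#: minimum pairwise center distance, in units of the within-cluster sd
_SEPARATION = 10.0


@dataclass
class SyntheticCohort:
    """A multi-layer synthetic cohort with ground-truth cluster labels."""

    truth_labels: np.ndarray
    layers: list[FeatureMatrix]
    n: int
    p: int
    k: int
    blob_sd: float
    noise_sd: list[float] = field(default_factory=list)
    missing_fraction: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.truth_labels = np.asarray(self.truth_labels, dtype=int)
        if not self.noise_sd:
            self.noise_sd = [0.0] * len(self.layers)
        if not self.missing_fraction:
            self.missing_fraction = [0.0] * len(self.layers)

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            self.truth_labels.copy(),
            [m.copy() for m in self.layers],
            self.n,
            self.p,
            self.k,
            self.blob_sd,
            list(self.noise_sd),
            list(self.missing_fraction),
            self.seed,
        )


def _centers(k: int, p: int, blob_sd: float) -> np.ndarray:
    """Cluster centers at scaled coordinate-axis vertices.

    Center j sits at ``scale * e_j``; pairwise distance is ``scale * sqrt(2)``
    which is kept >= _SEPARATION * blob_sd so the noiseless problem is
    unambiguous. The scale additionally grows with ``(p / k) ** 0.25`` so the
    center separation stays visible against the aggregate spread over the
    p - k non-informative coordinates (pairwise distances concentrate in high
    dimension). A floor of 1.0 keeps centers distinct when blob_sd == 0.
    """
    if k > p:
        raise ValueError(f"k={k} clusters need at least k feature dimensions (p={p})")
    scale = max(_SEPARATION * blob_sd * (p / k) ** 0.25, 1.0)
    c = np.zeros((k, p))
    for j in range(k):
        c[j, j] = scale
    return c


def make_blobs(
    n: int, p: int, k: int, blob_sd: float, seed: int = 0
) -> SyntheticCohort:
    """Generate a single noiseless layer of ``k`` isotropic Gaussian clusters.

    Cluster sizes are as equal as divisibility allows; samples are ordered by
    cluster.
    """
    if n < 1 or p < 1 or k < 1:
        raise ValueError("n, p and k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if blob_sd < 0:
        raise ValueError("blob_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(k), sizes)
    centers = _centers(k, p, blob_sd)
    values = centers[labels] + rng.normal(0.0, blob_sd, size=(n, p))
    width = max(3, len(str(n - 1)))
    fm = FeatureMatrix(
        values,
        [f"s{i:0{width}d}" for i in range(n)],
        [f"f{j:0{max(3, len(str(p - 1)))}d}" for j in range(p)],
        "layer0",
    )
    return SyntheticCohort(labels, [fm], n, p, k, blob_sd, seed=seed)


def replicate_layer(cohort: SyntheticCohort, t: int) -> SyntheticCohort:
    """Return a cohort whose first layer is duplicated into ``t`` layers.

    Mirrors the simulation design where every data type starts from the same
    ground-truth matrix before type-specific noise is added.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    out = cohort.copy()
    base = out.layers[0]
    out.layers = []
    for i in range(t):
        m = base.copy()
        m.layer_name = f"layer{i}"
        out.layers.append(m)
    out.noise_sd = [out.noise_sd[0] if cohort.noise_sd else 0.0] * t
    out.missing_fraction = [0.0] * t
    return out


def add_noise(
    cohort: SyntheticCohort, layer: int, noise_sd: float, seed: int = 0
) -> SyntheticCohort:
    """Add entrywise N(0, noise_sd^2) noise to one layer; others untouched."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not 0 <= layer < len(cohort.layers):
        raise IndexError(f"layer {layer} out of range")
    out = cohort.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out.layers[layer].values = out.layers[layer].values + rng.normal(
            0.0, noise_sd, size=out.layers[layer].values.shape
        )
    out.noise_sd[layer] = float(np.hypot(out.noise_sd[layer], noise_sd))
    return out


def drop_samples(
    cohort: SyntheticCohort, layer: int, fraction: float, seed: int = 0
) -> SyntheticCohort:
    """Make ``floor(fraction * n)`` random samples fully absent in one layer.

    The sample roster and all other layers are unchanged; absence is
    represented as an all-NaN row.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if not 0 <= layer < len(cohort.layers):
        raise IndexError(f"layer {layer} out of range")
    out = cohort.copy()
    n_drop = int(np.floor(fraction * cohort.n))
    if n_drop:
        rng = np.random.default_rng(seed)
        idx = rng.choice(cohort.n, size=n_drop, replace=False)
        out.layers[layer].values[idx, :] = np.nan
    out.missing_fraction[layer] = fraction
    return out


def default_pipeline_method(
    r: int | None = None,
    n_runs: int = 20,
    seed: int = 0,
    **cluster_kwargs,
):
    """Clustering callable for sweep experiments: the full integrative
    pipeline (similarity construction + resampled consensus) at rank ``r``
    (default: the cohort's true cluster count)."""
    from .consensus import cluster_network
    from .simnet import build_network

    def method(cohort: SyntheticCohort) -> np.ndarray:
        rank = r if r is not None else cohort.k
        net = build_network(cohort.layers)
        res = cluster_network(
            net, rank, n_runs=n_runs, n_subsets=0, seed=seed, **cluster_kwargs
        )
        return res.labels

    return method


def noise_sweep_experiment(
    base_noise: float,
    sweep: list[float],
    reps: int,
    method,
    seed: int = 0,
    n: int = 200,
    p: int = 400,
    k: int = 2,
    blob_sd: float = 0.5,
) -> pd.DataFrame:
    """Median-ARI curve over a grid of second-layer noise levels.

    For each sweep value, ``reps`` independent two-layer cohorts are built
    (both layers share the same ground-truth blobs; layer 1 gets
    ``base_noise``, layer 2 the sweep value), the clustering callable
    ``method(cohort) -> labels`` is run, and the median ARI against truth is
    reported. Failures of the callable on individual replicates are recorded,
    not fatal; a sweep value where every replicate fails raises.
    """
    from .evaluate import ari as _ari

    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(4 * len(sweep) * reps, dtype=np.uint32).tolist())
    rows = []
    for sval in sweep:
        scores: list[float] = []
        failures = 0
        for _ in range(reps):
            s_blob, s_n1, s_n2, _unused = (next(child) for _ in range(4))
            cohort = make_blobs(n, p, k, blob_sd, seed=s_blob)
            cohort = replicate_layer(cohort, 2)
            cohort = add_noise(cohort, 0, base_noise, seed=s_n1)
            cohort = add_noise(cohort, 1, sval, seed=s_n2)
            try:
                labels = method(cohort)
                scores.append(_ari(cohort.truth_labels, labels))
            except Exception:  # noqa: BLE001 - replicate failure is recorded
                logger.exception("method failed on replicate (sweep=%s)", sval)
                failures += 1
        if not scores:
            raise RuntimeError(f"method failed on every replicate at sweep={sval}")
        rows.append(
            {
                "noise_sd": sval,
                "median_ari": float(np.median(scores)),
                "n_ok": len(scores),
                "n_failed": failures,
            }
        )
    return pd.DataFrame(rows)
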