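"""Per-layer filtration, transformation, and standardization of feature matrices.

The canonical in-memory orientation is samples x features; on disk matrices
are stored transposed (features in rows, samples in columns — see
:mod:`omicsfuse.io`). Missing entries are represented as NaN throughout.

The intended pipeline order is filter -> transform -> standardize.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "filter_missing",
    "beta_to_m",
    "count_transform",
    "standardize",
]


@dataclass
class FeatureMatrix:
    """One omics layer: an ``n`` samples x ``p`` features real matrix.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Real-valued measurements; missing entries are NaN.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    feature_ids : list of str
        Unique feature identifiers, one per column.
    layer_name : str
        Human-readable name of the data type (e.g. ``"expression"``).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    layer_name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(),
            list(self.sample_ids),
            list(self.feature_ids),
            self.layer_name,
        )


def filter_missing(
    m: FeatureMatrix,
    max_missing_fraction: float = 0.1,
    axis: str = "features",
) -> FeatureMatrix:
    """Drop features (or samples) whose missing fraction exceeds a threshold.

    A row/column is retained iff ``missing_fraction <= max_missing_fraction``;
    the order of survivors is preserved.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    miss = np.isnan(m.values)
    if axis == "features":
        frac = miss.mean(axis=0)
        keep = frac <= max_missing_fraction
        if not keep.any():
            raise ValueError(
                f"all features exceed the missing-fraction threshold "
                f"{max_missing_fraction}"
            )
        return FeatureMatrix(
            m.values[:, keep],
            m.sample_ids,
            [f for f, k in zip(m.feature_ids, keep) if k],
            m.layer_name,
        )
    if axis == "samples":
        frac = miss.mean(axis=1)
        keep = frac <= max_missing_fraction
        if not keep.any():
            raise ValueError(
                f"all samples exceed the missing-fraction threshold "
                f"{max_missing_fraction}"
            )
        return FeatureMatrix(
            m.values[keep],
            [s for s, k in zip(m.sample_ids, keep) if k],
            m.feature_ids,
            m.layer_name,
        )
    raise ValueError(f"axis must be 'features' or 'samples', got {axis!r}")


def beta_to_m(m: FeatureMatrix, clip_eps: float = 1e-6) -> FeatureMatrix:
    """Convert methylation beta values to M-values, ``log2(b / (1 - b))``.

    Values are clipped to ``[clip_eps, 1 - clip_eps]`` first so the transform
    is defined at 0 and 1. Missing entries propagate.
    """
    if not 0.0 < clip_eps < 0.5:
        raise ValueError("clip_eps must be in (0, 0.5)")
    v = m.values
    with np.errstate(invalid="ignore"):
        bad = (v < 0.0) | (v > 1.0)
    if bad.any():
        raise ValueError("beta values outside [0, 1] found before clipping")
    b = np.clip(v, clip_eps, 1.0 - clip_eps)
    out = np.log2(b / (1.0 - b))
    out[np.isnan(v)] = np.nan
    return replace(m.copy(), values=out)


def count_transform(m: FeatureMatrix) -> FeatureMatrix:
    """Log-based surrogate for a variance-stabilizing count transform.

    Per-sample median-of-ratios size factors (ratios against the per-feature
    geometric mean over samples, restricted to features observed and positive
    in every sample) followed by ``log2(count / size_factor + 1)``. The
    transform is monotone in the counts within each sample. This is a
    documented simplification, not an exact reimplementation of model-based
    variance stabilization.
    """
    v = m.values
    with np.errstate(invalid="ignore"):
        if (v < 0).any():
            raise ValueError("count_transform requires nonnegative values")
    n = v.shape[0]
    # features usable for size-factor estimation: positive and observed everywhere
    usable = np.all(np.isfinite(v) & (v > 0), axis=0)
    size = np.ones(n)
    if usable.any():
        logv = np.log(v[:, usable])
        log_geo = logv.mean(axis=0)
        size = np.exp(np.median(logv - log_geo[None, :], axis=1))
    else:
        logger.warning(
            "layer %s: no feature is positive in every sample; "
            "size factors default to 1",
            m.layer_name,
        )
    out = np.log2(v / size[:, None] + 1.0)
    return replace(m.copy(), values=out)


def standardize(m: FeatureMatrix) -> FeatureMatrix:
    """Per-feature z-scores over non-missing entries (ddof=1).

    Constant features (or features with fewer than two observed values) carry
    no distance information and are dropped with a warning.
    """
    v = m.values
    obs = ~np.isnan(v)
    n_obs = obs.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(v, axis=0)
        sd = np.nanstd(v, axis=0, ddof=1)
    keep = (n_obs >= 2) & np.isfinite(sd) & (sd > 0)
    if not keep.all():
        dropped = [f for f, k in zip(m.feature_ids, keep) if not k]
        logger.warning(
            "layer %s: dropping %d constant/underpopulated feature(s): %s%s",
            m.layer_name,
            len(dropped),
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    if not keep.any():
        raise ValueError("standardize removed every feature")
    out = (v[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(
        out,
        m.sample_ids,
        [f for f, k in zip(m.feature_ids, keep) if k],
        m.layer_name,
    )
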