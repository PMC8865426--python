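"""External comparison of two labelings: ARI, NMI, purity, contingency."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["LabelComparison", "ari", "nmi", "purity", "compare"]


@dataclass
class LabelComparison:
    ari: float
    nmi: float
    purity: float
    contingency: np.ndarray


def _check(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (chance-corrected pair agreement)."""
    a, b = _check(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information with arithmetic-mean normalization.

    Returns 0 when either partition is trivial (single class).
    """
    a, b = _check(labels_a, labels_b)
    if len(set(a)) == 1 or len(set(b)) == 1:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def purity(labels_a, labels_b) -> float:
    """Fraction of samples in the majority reference class of their cluster.

    ``labels_a`` are the predicted clusters, ``labels_b`` the reference.
    """
    a, b = _check(labels_a, labels_b)
    ct = contingency_matrix(b, a)  # rows = reference, cols = predicted
    return float(ct.max(axis=0).sum() / ct.sum())


def compare(labels_a, labels_b) -> LabelComparison:
    a, b = _check(labels_a, labels_b)
    return LabelComparison(
        ari=ari(a, b),
        nmi=nmi(a, b),
        purity=purity(a, b),
        contingency=contingency_matrix(a, b),
    )
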