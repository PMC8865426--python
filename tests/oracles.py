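"""Independent brute-force oracles used to validate the package.

Everything here is written from first principles (plain loops, enumeration,
batched projected gradient) and deliberately shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# similarity construction


def rbf_network_bruteforce(X: np.ndarray, mu: float, K: int):
    """Step-by-step locally scaled RBF similarity for a complete matrix.

    Plain double loops: Euclidean distances, mean of the K smallest
    neighbor distances, kernel evaluation. Returns (A, D, eps).
    """
    n, p = X.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = math.sqrt(sum((X[i, m] - X[j, m]) ** 2 for m in range(p)))
    eps = np.zeros(n)
    for i in range(n):
        others = sorted(D[i, j] for j in range(n) if j != i)
        eps[i] = sum(others[:K]) / K
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                A[i, j] = 1.0
            else:
                A[i, j] = math.exp(-(D[i, j] ** 2) / (mu * eps[i] * eps[j]))
    return A, D, eps


def spearman_similarity_bruteforce(X: np.ndarray) -> np.ndarray:
    """Rank-and-correlate similarity mapped to [0, 1], loops only."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    def pearson(a, b):
        n = len(a)
        ma, mb = sum(a) / n, sum(b) / n
        num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        da = math.sqrt(sum((x - ma) ** 2 for x in a))
        db = math.sqrt(sum((y - mb) ** 2 for y in b))
        return num / (da * db)

    n = X.shape[0]
    A = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                r = pearson(ranks(list(X[i])), ranks(list(X[j])))
                A[i, j] = (1.0 + r) / 2.0
    return A


# ---------------------------------------------------------------------------
# factorization


def objective_bruteforce(A_list, W_list, lam_list, H, S_list, eta) -> float:
    """Element-by-element double-loop evaluation of the masked objective."""
    total = 0.0
    n, r = H.shape
    for A, W, lam, S in zip(A_list, W_list, lam_list, S_list):
        for x in range(n):
            for y in range(n):
                if W[x, y] > 0:
                    approx = sum(
                        H[x, a] * S[a, b] * H[y, b]
                        for a in range(r)
                        for b in range(r)
                    )
                    total += lam * (A[x, y] - approx) ** 2
    total += eta * sum(H[x, a] ** 2 for x in range(n) for a in range(r))
    return total


def update_S_bruteforce(H, S, A, W, guard=1e-12):
    """Naive evaluation of the multiplicative core update."""
    n, r = H.shape
    WA = np.zeros((n, n))
    Wapprox = np.zeros((n, n))
    approx = H @ S @ H.T
    for x in range(n):
        for y in range(n):
            if W[x, y] > 0:
                WA[x, y] = A[x, y]
                Wapprox[x, y] = approx[x, y]
    num = H.T @ WA @ H
    den = H.T @ Wapprox @ H + guard
    return S * num / den


def update_H_bruteforce(H, S_list, A_list, W_list, lam_list, eta, guard=1e-12):
    """Naive evaluation of the multiplicative shared-factor update."""
    num = np.zeros_like(H)
    den = np.full_like(H, guard)
    for A, W, lam, S in zip(A_list, W_list, lam_list, S_list):
        WA = np.where(W > 0, A, 0.0)
        Wapprox = np.where(W > 0, H @ S @ H.T, 0.0)
        num = num + lam * (WA @ H @ S)
        den = den + lam * (Wapprox @ H @ S)
    den = den + 0.5 * eta * H
    return H * num / den


def projected_gradient_restarts(
    A: np.ndarray,
    r: int,
    eta: float,
    n_restarts: int,
    seed: int = 0,
    n_iter: int = 400,
) -> float:
    """Best objective over many random-restart projected-gradient runs.

    Single complete layer, lam = n^-2. All restarts run simultaneously
    (batched arrays) with per-restart backtracking step sizes. Returns the
    minimum objective value found.
    """
    n = A.shape[0]
    lam = 1.0 / n**2
    rng = np.random.default_rng(seed)
    B = n_restarts
    H = rng.uniform(0.0, 1.0, size=(B, n, r))
    S = rng.uniform(0.0, 1.0, size=(B, r, r))
    S = (S + np.transpose(S, (0, 2, 1))) / 2.0

    def objective(H, S):
        E = A[None] - np.einsum("bnr,brs,bms->bnm", H, S, H)
        return lam * np.einsum("bnm,bnm->b", E, E) + eta * np.einsum(
            "bnr,bnr->b", H, H
        )

    step = np.full(B, 1.0)
    L = objective(H, S)
    for _ in range(n_iter):
        E = A[None] - np.einsum("bnr,brs,bms->bnm", H, S, H)
        Ssym = S + np.transpose(S, (0, 2, 1))
        gH = -2.0 * lam * np.einsum("bnm,bms,bsr->bnr", E, H, Ssym) + 2.0 * eta * H
        gS = -2.0 * lam * np.einsum("bnr,bnm,bms->brs", H, E, H)
        accepted = np.zeros(B, dtype=bool)
        for _bt in range(12):
            st = step[:, None, None]
            Hc = np.where(accepted[:, None, None], H, np.maximum(H - st * gH, 0.0))
            Sc = np.where(accepted[:, None, None], S, np.maximum(S - st * gS, 0.0))
            Lc = objective(Hc, Sc)
            better = ~accepted & (Lc <= L + 1e-15)
            H = np.where(better[:, None, None], Hc, H)
            S = np.where(better[:, None, None], Sc, S)
            L = np.where(better, Lc, L)
            accepted |= better
            step = np.where(accepted, step, step * 0.5)
            if accepted.all():
                break
        step = np.where(accepted, step * 1.1, step)
    return float(L.min())


# ---------------------------------------------------------------------------
# consensus machinery


def weighted_consensus_bruteforce(runs, n: int) -> np.ndarray:
    """Hand-rolled weighted consensus: runs = list of (indices, labels, RE)."""
    res = [re for _, _, re in runs]
    M, N = max(res), min(res)
    weights = [1.0 if M == N else (M - re) / (M - N) for re in res]
    C = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            num = den = 0.0
            for (idx, lab, _), w in zip(runs, weights):
                pos = {s: i for i, s in enumerate(idx)}
                if a in pos and b in pos:
                    den += w
                    if lab[pos[a]] == lab[pos[b]]:
                        num += w
            C[a, b] = num / den if den > 0 else 0.0
    np.fill_diagonal(C, 1.0)
    return C


def ncut_value(A: np.ndarray, labels) -> float:
    """Normalized-cut objective of a partition (sum of cut/assoc terms)."""
    labels = np.asarray(labels)
    d = A.sum(axis=1)
    total = 0.0
    for c in np.unique(labels):
        inside = labels == c
        assoc = d[inside].sum()
        cut = A[np.ix_(inside, ~inside)].sum()
        if assoc == 0:
            return float("inf")
        total += cut / assoc
    return total


def best_bipartition(A: np.ndarray):
    """Exhaustive minimum-normalized-cut search over all 2-way partitions."""
    n = A.shape[0]
    best, best_lab = float("inf"), None
    for bits in range(1, 2 ** (n - 1)):
        lab = np.array([(bits >> i) & 1 for i in range(n)])
        v = ncut_value(A, lab)
        if v < best:
            best, best_lab = v, lab
    return best_lab, best


def cophenetic_matrix_from_linkage(Z: np.ndarray, n: int) -> np.ndarray:
    """Cophenetic distances by direct traversal of a scipy linkage matrix."""
    members = {i: [i] for i in range(n)}
    D = np.zeros((n, n))
    for step in range(Z.shape[0]):
        a, b, height = int(Z[step, 0]), int(Z[step, 1]), Z[step, 2]
        for x in members[a]:
            for y in members[b]:
                D[x, y] = D[y, x] = height
        members[n + step] = members[a] + members[b]
        del members[a], members[b]
    return D


def pair_counting_ari(a, b) -> float:
    """ARI by explicit enumeration of all sample pairs."""
    a, b = list(a), list(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    index = ss
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2.0
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)
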