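"""Masked joint symmetric tri-factorization by multiplicative updates.

Each similarity matrix is approximated as ``A_i ~= H S_i H^T`` with one
shared nonnegative factor ``H`` (n x r) and per-layer nonnegative cores
``S_i`` (r x r), minimizing

    L = sum_i lambda_i || W_i o (A_i - H S_i H^T) ||_F^2 + eta ||H||_F^2

where ``o`` is the entrywise product and ``W_i`` masks unavailable entries
out of both the objective and every update. The solver alternates
multiplicative updates for all ``S_i`` and for ``H`` from an SVD-based
initialization until the relative objective change drops below a tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simnet import MultiplexNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "FactorizationResult",
    "objective",
    "residual_error",
    "svd_init",
    "update_S",
    "update_H",
    "factorize",
    "hard_labels",
]

#: additive guard in every multiplicative-update denominator
DENOM_GUARD = 1e-12
#: exact zeros in the initialization are lifted to this fraction of the mean
#: positive entry (multiplicative updates cannot escape exact zeros)
ZERO_LIFT = 1e-8
#: the eta penalty induces a slow uniform shrink of H (S grows to
#: compensate, leaving the data fit unchanged); once H's largest entry falls
#: below this floor the iteration is in pure scale drift and further updates
#: only risk underflowing rows to exact zero, so the solver stops
H_COLLAPSE_FLOOR = 1e-100


@dataclass
class SolverConfig:
    """Hyperparameters of the tri-factorization solver."""

    r: int = 2
    eta: float = 0.1
    tol: float = 1e-7
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FactorizationResult:
    """Output of one solver run."""

    H: np.ndarray
    S_list: list[np.ndarray]
    objective_trace: list[float] = field(default_factory=list)
    RE: float = np.nan
    iterations: int = 0
    converged: bool = False

    def labels(self) -> np.ndarray:
        return hard_labels(self.H)


def _masked_layers(network: MultiplexNetwork):
    """Per layer: (W, W o A with NaN->0, lambda)."""
    out = []
    for lay in network.layers:
        W = (lay.W > 0).astype(float)
        WA = np.where(W > 0, np.nan_to_num(lay.A), 0.0)
        out.append((W, WA, lay.lambda_weight))
    return out


def objective(
    network: MultiplexNetwork,
    H: np.ndarray,
    S_list: list[np.ndarray],
    eta: float,
) -> float:
    """Evaluate the masked objective L; unavailable entries contribute 0."""
    return _objective_terms(_masked_layers(network), H, S_list, eta)[0]


def residual_error(
    network: MultiplexNetwork, H: np.ndarray, S_list: list[np.ndarray]
) -> float:
    """Data-fit term only: RE = sum_i lambda_i ||W_i o (A_i - H S_i H^T)||_F^2."""
    return _objective_terms(_masked_layers(network), H, S_list, 0.0)[1]


def _objective_terms(masked, H, S_list, eta):
    if len(masked) != len(S_list):
        raise ValueError("one core matrix per layer required")
    re = 0.0
    for (W, WA, lam), S in zip(masked, S_list):
        if H.shape[1] != S.shape[0] or S.shape[0] != S.shape[1]:
            raise ValueError("nonconforming factor shapes")
        approx = H @ S @ H.T
        re += lam * float(np.sum((W * (WA - W * approx)) ** 2))
    return re + eta * float(np.sum(H**2)), re


def svd_init(network: MultiplexNetwork, r: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Deterministic SVD-based initialization.

    ``H0`` is the entrywise absolute value of the r leading left singular
    vectors of the mask-aware mean similarity matrix (mean over layers of
    available entries). Each ``S0_i`` is diagonal with the r leading absolute
    singular values of ``A_i`` (unavailable entries treated as 0).
    """
    n = network.n
    if r > n:
        raise ValueError(f"r={r} exceeds n={n}")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for lay in network.layers:
        W = (lay.W > 0).astype(float)
        num += np.where(W > 0, np.nan_to_num(lay.A), 0.0)
        den += W
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_A = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
    U, sv, _ = np.linalg.svd(mean_A, hermitian=False)
    rank = int((sv > sv[0] * 1e-12).sum()) if sv.size else 0
    if rank < r:
        logger.warning("mean similarity has rank %d < r=%d; zero-padding", rank, r)
    H0 = np.abs(U[:, :r])
    S0_list = []
    for lay in network.layers:
        A0 = np.where(lay.W > 0, np.nan_to_num(lay.A), 0.0)
        sv_i = np.linalg.svd(A0, compute_uv=False)
        d = np.zeros(r)
        m = min(r, sv_i.size)
        d[:m] = np.abs(sv_i[:m])
        S0_list.append(np.diag(d))
    return H0, S0_list


def _lift_zeros(M: np.ndarray) -> np.ndarray:
    pos = M[M > 0]
    floor = ZERO_LIFT * (pos.mean() if pos.size else 1.0)
    out = M.copy()
    out[out <= 0] = floor
    return out


def update_S(
    H: np.ndarray, S: np.ndarray, A: np.ndarray, W: np.ndarray
) -> np.ndarray:
    """One multiplicative update of a layer core:

    ``S <- S o [H^T (W o A) H] / [H^T (W o (H S H^T)) H + guard]``.
    """
    Wb = (W > 0).astype(float)
    WA = np.where(Wb > 0, np.nan_to_num(A), 0.0)
    num = H.T @ WA @ H
    den = H.T @ (Wb * (H @ S @ H.T)) @ H + DENOM_GUARD
    return S * num / den


def update_H(
    H: np.ndarray,
    S_list: list[np.ndarray],
    network: MultiplexNetwork,
    eta: float,
) -> np.ndarray:
    """One multiplicative update of the shared factor:

    ``H <- H o [sum_i l_i (W_i o A_i) H S_i] /
    [sum_i l_i (W_i o (H S_i H^T)) H S_i + 0.5 eta H + guard]``.
    """
    masked = _masked_layers(network)
    return _update_H_masked(H, S_list, masked, eta)


def _update_H_masked(H, S_list, masked, eta):
    num = np.zeros_like(H)
    den = np.full_like(H, DENOM_GUARD)
    for (W, WA, lam), S in zip(masked, S_list):
        HS = H @ S
        num += lam * (WA @ HS)
        den += lam * ((W * (HS @ H.T)) @ HS)
    den += 0.5 * eta * H
    return H * num / den


def _geometric_mix(old: np.ndarray, new: np.ndarray, gamma: float) -> np.ndarray:
    """Entrywise ``old * (new / old) ** gamma`` (damped multiplicative step)."""
    ratio = np.where(old > 0, new / np.maximum(old, 1e-300), 1.0)
    return old * ratio**gamma


def _damp_step_H(masked, H_old, H_new, S_list, eta, L_ref):
    """Backtrack the H step until the objective is non-increasing."""
    gamma = 0.5
    for _ in range(30):
        H_try = _geometric_mix(H_old, H_new, gamma)
        L_try = _objective_terms(masked, H_try, S_list, eta)[0]
        if L_try <= L_ref:
            return H_try, L_try
        gamma *= 0.5
    logger.debug("H backtracking exhausted; keeping previous iterate")
    return H_old, L_ref


def _damp_step_S(masked, H, S_old, S_new, eta, L_ref):
    """Backtrack the S sweep until the objective is non-increasing."""
    gamma = 0.5
    for _ in range(30):
        S_try = [
            _geometric_mix(o, n, gamma) for o, n in zip(S_old, S_new)
        ]
        if _objective_terms(masked, H, S_try, eta)[0] <= L_ref:
            return S_try
        gamma *= 0.5
    logger.debug("S backtracking exhausted; keeping previous iterates")
    return S_old


def factorize(
    network: MultiplexNetwork,
    config: SolverConfig,
    init: tuple[np.ndarray, list[np.ndarray]] | None = None,
) -> FactorizationResult:
    """Run the alternating multiplicative-update solver.

    Parameters
    ----------
    init : optional (H0, S0_list)
        Override the deterministic SVD initialization (the consensus stage
        passes randomly perturbed cores here). Zeros are lifted either way.

    Raises
    ------
    RuntimeError
        If the objective rises between iterations beyond a 1e-8 relative
        tolerance — that indicates a broken update, never a valid state.
    """
    if init is None:
        H, S_list = svd_init(network, config.r)
    else:
        H, S_list = init
        H = np.asarray(H, dtype=float)
        S_list = [np.asarray(S, dtype=float) for S in S_list]
    H = _lift_zeros(H)
    S_list = [_lift_zeros(S) for S in S_list]

    masked = _masked_layers(network)
    trace: list[float] = []
    L_prev = _objective_terms(masked, H, S_list, config.eta)[0]
    trace.append(L_prev)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        S_old = S_list
        S_list = []
        for j, (W, WA, lam) in enumerate(masked):
            S = S_old[j]
            num = H.T @ WA @ H
            den = H.T @ (W * (H @ S @ H.T)) @ H + DENOM_GUARD
            S_list.append(S * num / den)
        L_mid = _objective_terms(masked, H, S_list, config.eta)[0]
        if L_mid > L_prev:
            S_list = _damp_step_S(
                masked, H, S_old, S_list, config.eta, L_prev
            )
            L_mid = _objective_terms(masked, H, S_list, config.eta)[0]
        H_new = _update_H_masked(H, S_list, masked, config.eta)
        L = _objective_terms(masked, H_new, S_list, config.eta)[0]
        if L > L_mid:
            # the quartic H subproblem can overshoot; damp the
            # multiplicative step geometrically until non-increasing
            # (fixed points are unchanged)
            H_new, L = _damp_step_H(masked, H, H_new, S_list, config.eta, L_mid)
        H = H_new
        trace.append(L)
        if L > L_prev * (1.0 + 1e-8) + 1e-12:
            raise RuntimeError(
                f"objective increased at iteration {it}: {L_prev} -> {L}"
            )
        denom = L if L > 0 else 1.0
        if abs(L - L_prev) / denom < config.tol:
            converged = True
            L_prev = L
            break
        L_prev = L
        if H.max() < H_COLLAPSE_FLOOR:
            logger.debug("H scale collapsed below %.0e; stopping", H_COLLAPSE_FLOOR)
            break
    re = _objective_terms(masked, H, S_list, 0.0)[1]
    return FactorizationResult(
        H=H,
        S_list=S_list,
        objective_trace=trace,
        RE=re,
        iterations=it,
        converged=converged,
    )


def hard_labels(H: np.ndarray) -> np.ndarray:
    """Assign each sample to the column of H holding its row maximum.

    Ties break toward the smallest column index (np.argmax convention);
    all-zero rows go to column 0 with a warning.
    """
    if H.ndim != 2 or H.shape[1] < 1:
        raise ValueError("H must have at least one column")
    zero_rows = ~(H > 0).any(axis=1)
    if zero_rows.any():
        logger.warning("%d all-zero row(s) in H assigned to cluster 0", int(zero_rows.sum()))
    return np.argmax(H, axis=1)
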