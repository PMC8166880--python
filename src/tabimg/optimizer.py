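"""Iterative feature-swap minimization of the rank-difference error.

The objective is

    err(R, Q) = sum_{i>j} diff(r_ij, q_ij)

over the strict lower triangle, with ``diff`` either the absolute or the
squared difference.  A swap of two features exchanges the corresponding
rows and columns of ``R`` simultaneously, so the error change can be
computed touching only those two rows/columns — an O(N) update instead of
an O(N^2) recomputation, which is what makes the search practical.

Each iteration picks the feature that has waited longest since it was
last considered (round-robin fairness via the ``h`` bookkeeping vector),
finds its best swap partner, and accepts the swap when the relative error
reduction exceeds ``t_swap``.  A non-negative ``t_swap`` makes the error
trace monotonically non-increasing; a negative one permits uphill moves
to escape local optima.  The algorithm is fully deterministic: all ties
are broken by smallest index, so no random source is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ranking import RankMatrix, as_rank_array

__all__ = [
    "IGTDConfig",
    "OptimizationResult",
    "err",
    "swap_error_delta",
    "best_swap_for",
    "apply_ordering",
    "igtd_optimize",
]

DIFF_FNS = ("absolute", "squared")


@dataclass(frozen=True)
class IGTDConfig:
    """Optimizer hyper-parameters.

    ``s_max``: iteration cap.  ``s_con``/``t_con``: the run is declared
    converged when the relative error reduction against the error
    ``s_con`` iterations ago stays below ``t_con`` for ``s_con``
    consecutive iterations.  ``t_swap``: relative-reduction threshold a
    candidate swap must beat to be accepted (may be negative).
    """

    s_max: int = 30_000
    s_con: int = 500
    t_con: float = 1e-6
    t_swap: float = 0.0
    diff_fn: str = "absolute"

    def __post_init__(self) -> None:
        if self.s_con < 1:
            raise ValueError("s_con must be positive")
        if self.s_max < 2 * self.s_con:
            raise ValueError("s_max must be at least 2 * s_con")
        if self.t_con <= 0:
            raise ValueError("t_con must be positive")
        if self.diff_fn not in DIFF_FNS:
            raise ValueError(f"diff_fn must be one of {DIFF_FNS}")


@dataclass
class OptimizationResult:
    """Outcome of a layout optimization run.

    ``ordering[p]`` is the original feature index assigned to linear pixel
    position ``p``; applying it to the initial rank matrix reproduces
    ``error`` exactly.
    """

    ordering: np.ndarray
    error: float
    error_trace: np.ndarray
    n_iterations: int
    converged: bool
    best_iteration: int
    #: per-iteration record of (candidate feature, best partner, accepted)
    moves: list = field(default_factory=list, repr=False)


def _diff(a: np.ndarray, b: np.ndarray, diff_fn: str) -> np.ndarray:
    if diff_fn == "absolute":
        return np.abs(a - b)
    if diff_fn == "squared":
        return (a - b) ** 2
    raise ValueError(f"diff_fn must be one of {DIFF_FNS}")


def err(R, Q, diff_fn: str = "absolute") -> float:
    """Total rank discrepancy over the strict lower triangle."""
    r, q = as_rank_array(R), as_rank_array(Q)
    if r.shape != q.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {q.shape}")
    i, j = np.tril_indices(r.shape[0], k=-1)
    return float(_diff(r[i, j], q[i, j], diff_fn).sum())


def _all_swap_deltas(r: np.ndarray, q: np.ndarray, n: int, diff_fn: str) -> np.ndarray:
    """Error reduction achieved by swapping feature ``n`` with each other feature.

    For the swap (n, l) only entries in rows/columns n and l change; the
    (n, l) entry itself is invariant.  Writing a_j = diff(r_nj, q_nj),

        delta_l = sum_{j not in {n,l}} [ a_j + diff(r_lj, q_lj)
                                         - diff(r_lj, q_nj) - diff(r_nj, q_lj) ]

    which this computes for every l at once with dense array ops.
    """
    B = _diff(r, q, diff_fn)                 # B[l, j] = diff(r_lj, q_lj)
    C = _diff(r, q[n][None, :], diff_fn)     # C[l, j] = diff(r_lj, q_nj)
    D = _diff(r[n][None, :], q, diff_fn)     # D[l, j] = diff(r_nj, q_lj)
    S = B + B[n][None, :] - C - D
    deltas = S.sum(axis=1) - S[:, n] - np.diag(S)
    deltas[n] = -np.inf  # swapping with itself is not a move
    return deltas


def swap_error_delta(R, Q, n: int, l: int, diff_fn: str = "absolute") -> float:
    """err(R, Q) - err(R with features n and l swapped, Q).

    Positive means the swap reduces the error.  Touches only the rows and
    columns of the two features; equals the full recomputation exactly.
    """
    if n == l:
        raise ValueError("cannot swap a feature with itself")
    r, q = as_rank_array(R), as_rank_array(Q)
    mask = np.ones(r.shape[0], dtype=bool)
    mask[[n, l]] = False
    a = _diff(r[n, mask], q[n, mask], diff_fn)
    b = _diff(r[l, mask], q[l, mask], diff_fn)
    c = _diff(r[l, mask], q[n, mask], diff_fn)
    d = _diff(r[n, mask], q[l, mask], diff_fn)
    return float((a + b - c - d).sum())


def best_swap_for(R, Q, n_star: int, diff_fn: str = "absolute") -> tuple[int, float]:
    """Swap partner of ``n_star`` with the largest error reduction.

    Ties are broken by smallest partner index.  The returned delta may be
    negative when every swap would increase the error.
    """
    r, q = as_rank_array(R), as_rank_array(Q)
    deltas = _all_swap_deltas(r, q, n_star, diff_fn)
    l_star = int(np.argmax(deltas))  # argmax returns the first (smallest) index on ties
    return l_star, float(deltas[l_star])


def apply_ordering(R0, ordering: np.ndarray) -> RankMatrix:
    """Permute rows and columns of ``R0`` identically by ``ordering``."""
    r = as_rank_array(R0)
    perm = np.asarray(ordering, dtype=int)
    n = r.shape[0]
    if perm.shape != (n,) or not np.array_equal(np.sort(perm), np.arange(n)):
        raise ValueError("ordering must be a permutation of 0..N-1")
    return RankMatrix(r[np.ix_(perm, perm)])


def igtd_optimize(R, Q, cfg: IGTDConfig | None = None) -> OptimizationResult:
    """Minimize err(R, Q) over synchronized row/column permutations of R.

    Returns the ordering and error of the best iteration seen (earliest on
    ties).  ``error_trace[s]`` is the error after iteration ``s`` (index 0
    is the initial error).
    """
    cfg = cfg or IGTDConfig()
    r0 = as_rank_array(R)
    q = as_rank_array(Q)
    if r0.shape != q.shape:
        raise ValueError(f"shape mismatch: {r0.shape} vs {q.shape}")
    n = r0.shape[0]
    r = r0.copy()

    e0 = err(r, q, cfg.diff_fn)
    trace = [e0]
    moves: list[tuple[int, int, bool]] = []
    if e0 == 0.0:
        return OptimizationResult(np.arange(n), 0.0, np.array(trace), 0, True, 0, moves)

    # h[f]: last iteration at which feature f was considered for a swap.
    # -inf start with smallest-index tie-breaking means the first sweep
    # simply visits features in index order.
    h = np.full(n, -np.inf)
    k = np.arange(n)
    converged = False
    s = 0
    while s < cfg.s_max:
        s += 1
        e_prev = trace[-1]
        if e_prev == 0.0:
            converged = True  # exact match reached; ratios below are undefined
            s -= 1
            break
        n_star = int(np.argmin(h))
        deltas = _all_swap_deltas(r, q, n_star, cfg.diff_fn)
        l_star = int(np.argmax(deltas))
        delta = float(deltas[l_star])
        if delta / e_prev > cfg.t_swap:
            k[n_star], k[l_star] = k[l_star], k[n_star]
            r[[n_star, l_star], :] = r[[l_star, n_star], :]
            r[:, [n_star, l_star]] = r[:, [l_star, n_star]]
            h[n_star] = h[l_star] = s
            trace.append(e_prev - delta)
            moves.append((n_star, l_star, True))
        else:
            h[n_star] = s
            trace.append(e_prev)
            moves.append((n_star, l_star, False))
        if s > cfg.s_con:
            base = trace[s - cfg.s_con]
            if base == 0.0:
                converged = True
                break
            window = np.array(trace[s - cfg.s_con + 1: s + 1])
            if np.all((base - window) / base < cfg.t_con):
                converged = True
                break

    trace_arr = np.array(trace)
    v_star = int(np.argmin(trace_arr))  # earliest iteration on ties
    ordering = np.arange(n)
    for a, b, accepted in moves[:v_star]:
        if accepted:
            ordering[a], ordering[b] = ordering[b], ordering[a]
    return OptimizationResult(
        ordering=ordering,
        error=float(trace_arr[v_star]),
        error_trace=trace_arr,
        n_iterations=s,
        converged=converged,
        best_iteration=v_star,
        moves=moves,
    )
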