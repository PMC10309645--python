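"""Greedy sparse solvers for the L0-regularized FMT inverse problem.

The measurement model phi_m = A x is severely underdetermined and the
fluorescent target is spatially sparse, so reconstruction is posed as

    min ||x||_0   subject to   ||A x - phi_m||_2^2 < eps.

This module implements the neighbor-based adaptive sparsity orthogonal
least squares solver (NASOLS) together with the baselines it is compared
against: ASOLS (same adaptive schedule without the neighbor restriction),
fixed-sparsity OLS, OMP, generalized OMP and CoSaMP.

OLS machinery
-------------
Column selection uses deflated columns t_j: starting from t_j = a_j, after a
basis vector u is accepted every unselected column is deflated,
t_j <- t_j - (t_j.u/||u||^2) u, so t_j is always the component of a_j
orthogonal to the current basis.  A candidate's score is ||q_j||_2 with
q_j = (a_j.r / a_j.t_j) t_j — the orthogonal projection of the residual onto
the deflated direction — and the accepted update is u <- q_j, r <- r - u,
which makes the residual norm non-increasing by construction.

Adaptive schedule
-----------------
The target sparsity K_i and per-iteration selection width L_i follow
ceilinged quadratically-decaying steps

    K_i = K_{i-1} + ceil(K0/(i+1)^2),   L_i = L_{i-1} - ceil(L0/(i+1)^2)

(large steps early, unit steps late; L is floored at 1).  With the default
K0=6, L0=10 the sequences run K: 6,8,9,10,... and L: 10,7,5,4,...

Neighbor restriction
--------------------
NASOLS draws candidates only from the tetrahedral edge neighborhood N(S_i)
of the current support, exploiting that a fluorescent target occupies a
connected patch of mesh nodes; with a complete graph it reduces exactly to
ASOLS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy.linalg import lstsq

from .mesh import NeighborGraph, complete_graph, neighbor_set

__all__ = [
    "SolverConfig",
    "GreedyState",
    "Solution",
    "ols_scores",
    "deflate_columns",
    "update_schedule",
    "update_residual",
    "restricted_lsq",
    "nasols",
    "asols",
    "ols_fixed",
    "omp",
    "gomp",
    "cosamp",
]

logger = logging.getLogger("fmtrecon.solvers")

# relative floor under which a deflated direction counts as exhausted
DEFLATION_FLOOR = 1e-12


class DegenerateCandidatesError(RuntimeError):
    """All candidate columns have exhausted (near-zero) deflated directions."""


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------

@dataclass
class SolverConfig:
    """Settings shared by the greedy solvers.

    Parameters
    ----------
    K0 : int
        Initial sparsity estimate (default 6).
    L0 : int
        Initial selection width (default 10).
    eps : float
        Halting threshold on the residual 2-norm (default 1e-8).
    eps_mode : {"abs", "rel"}
        Interpret ``eps`` as an absolute norm (default, scale-fragile but
        conventional) or relative to ||y||.
    max_iter : int
        Cap on outer iterations of the adaptive loop.
    nonneg : bool
        Clamp negative entries of the final yield estimate to 0.
    rescore : bool
        Re-score the candidate set after each single selection within an
        iteration (default); ``False`` selects the iteration's L columns
        from one scoring pass.
    init_single_pass : bool
        Choose the initial L0-column support from a single scoring pass
        instead of re-scoring between initial selections (default False,
        the classical greedy behavior).  With the highly correlated columns
        of an FMT operator a single pass seeds a compact cluster around the
        energy peak, which the neighbor expansion then grows; the experiment
        pipeline therefore enables it.
    stall_tol : float
        Stagnation stop: halt the adaptive loop when an iteration reduces
        the residual norm by less than this fraction.  Measured data never
        reach an absolute eps (noise and forward-model mismatch put a floor
        under the residual), so without this stop the support would grow
        until max_iter.  0 disables.
    """

    K0: int = 6
    L0: int = 10
    eps: float = 1e-8
    eps_mode: str = "abs"
    max_iter: int = 50
    tie_break: str = "lowest-index"
    nonneg: bool = False
    rescore: bool = True
    init_single_pass: bool = False
    stall_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.K0 < 1 or self.L0 < 1:
            raise ValueError("K0 and L0 must be >= 1")
        if not (self.eps > 0):
            raise ValueError("eps must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.eps_mode not in ("abs", "rel"):
            raise ValueError("eps_mode must be 'abs' or 'rel'")
        if self.tie_break != "lowest-index":
            raise ValueError("only lowest-index tie-breaking is implemented")


@dataclass
class GreedyState:
    """Evolving OLS state: support S_i, residual r_i, basis {u}, deflated t_j."""

    A: np.ndarray                  # (m, n) measurement operator, read-only
    residual: np.ndarray           # r_i
    T: np.ndarray                  # deflated columns t_j (m, n), mutated in place
    support: list[int] = field(default_factory=list)
    basis: list[np.ndarray] = field(default_factory=list)
    candidates: set[int] = field(default_factory=set)
    iter: int = 0
    K_cur: int = 0
    L_cur: int = 0

    @classmethod
    def fresh(cls, A: np.ndarray, y: np.ndarray) -> "GreedyState":
        return cls(A=A, residual=np.array(y, dtype=float, copy=True),
                   T=np.array(A, dtype=float, copy=True))

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.residual))


@dataclass
class Solution:
    """Result of a greedy solve."""

    x_hat: np.ndarray
    support_final: list[int]
    residual_norm: float
    iterations: int
    converged: bool
    history: list[tuple[int, int, float]] = field(default_factory=list)  # (K_i, L_i, ||r_i||)
    support_all: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def ols_scores(A: np.ndarray, state: GreedyState,
               candidates: np.ndarray) -> np.ndarray:
    """OLS selection scores ||q_j||_2 for each candidate column.

    q_j = (a_j.r / a_j.t_j) t_j with t_j the deflated column.  Candidates
    whose deflated direction is numerically exhausted
    (|a_j.t_j| < 1e-12 ||a_j|| ||t_j||) score -inf and are excluded.
    """
    candidates = np.asarray(candidates, dtype=np.intp)
    if len(candidates) == 0:
        raise DegenerateCandidatesError("empty candidate set")
    Ac = A[:, candidates]
    Tc = state.T[:, candidates]
    num = Ac.T @ state.residual                 # a_j . r
    den = np.einsum("ij,ij->j", Ac, Tc)         # a_j . t_j
    t_norm = np.linalg.norm(Tc, axis=0)
    a_norm = np.linalg.norm(Ac, axis=0)
    ok = (np.abs(den) > 0) & (np.abs(den) >= DEFLATION_FLOOR * a_norm * t_norm)
    scores = np.full(len(candidates), -np.inf)
    # ||q_j|| = |a_j.r / a_j.t_j| * ||t_j||
    scores[ok] = np.abs(num[ok] / den[ok]) * t_norm[ok]
    if not np.any(ok):
        raise DegenerateCandidatesError("all candidate columns are exhausted")
    return scores


def q_vector(A: np.ndarray, state: GreedyState, j: int) -> np.ndarray:
    """The projection vector q_j of one column against the current state."""
    aj = A[:, j]
    tj = state.T[:, j]
    den = float(aj @ tj)
    return (float(aj @ state.residual) / den) * tj


def deflate_columns(state: GreedyState, u_new: np.ndarray) -> None:
    """Deflate every unselected column against a new basis vector (in place).

    t_j <- t_j - (t_j.u/||u||^2) u, after which t_j.u = 0 to round-off.
    """
    nrm2 = float(u_new @ u_new)
    if nrm2 == 0.0:
        raise ValueError("degenerate basis vector (zero norm)")
    coeff = (u_new @ state.T) / nrm2
    if state.support:
        coeff[np.asarray(state.support, dtype=np.intp)] = 0.0
    state.T -= np.outer(u_new, coeff)


def update_schedule(K_prev: int, L_prev: int, i: int,
                    K0: int, L0: int) -> tuple[int, int]:
    """One step of the adaptive sparsity schedule (i >= 1).

    K grows and L shrinks by ceilinged steps proportional to 1/(i+1)^2; L is
    floored at 1 because a selection width of 0 would stall the solver.
    """
    if i < 1:
        raise ValueError("iteration index must be >= 1")
    step = (i + 1) ** 2
    K_i = K_prev + ceil(K0 / step)
    L_i = max(1, L_prev - ceil(L0 / step))
    return K_i, L_i


def update_residual(state: GreedyState, q_selected: np.ndarray) -> None:
    """Accept q_j as the next basis vector and subtract it from the residual."""
    state.basis.append(np.array(q_selected, copy=True))
    state.residual -= q_selected


def restricted_lsq(A: np.ndarray, support: list[int] | np.ndarray,
                   y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares coefficients on a column subset, and the attained ||r||.

    Uses a rank-revealing (SVD) factorization; a rank-deficient restriction
    triggers a warning and yields the minimum-norm solution.
    """
    support = list(support)
    if len(support) == 0:
        raise ValueError("support must be nonempty")
    As = A[:, support]
    c, _, rank, _ = lstsq(As, y)
    if rank < len(support):
        warnings.warn("rank-deficient restricted system; minimum-norm solution",
                      RuntimeWarning, stacklevel=2)
    return c, float(np.linalg.norm(y - As @ c))


# ---------------------------------------------------------------------------
# shared greedy driver
# ---------------------------------------------------------------------------

def _select_one(state: GreedyState, candidates: set[int]) -> int | None:
    """Greedy-select the best candidate, apply r/basis/deflation updates."""
    cand = np.fromiter(sorted(candidates), dtype=np.intp, count=len(candidates))
    try:
        scores = ols_scores(state.A, state, cand)
    except DegenerateCandidatesError:
        return None
    j = int(cand[int(np.argmax(scores))])   # argmax keeps the lowest index on ties
    q = q_vector(state.A, state, j)
    update_residual(state, q)
    state.support.append(j)
    candidates.discard(j)
    deflate_columns(state, q)
    return j


def _select_batch(state: GreedyState, candidates: set[int], width: int,
                  eps_abs: float, rescore: bool, cap: int) -> int:
    """Select up to ``width`` columns from ``candidates``; returns how many."""
    width = min(width, len(candidates), cap - len(state.support))
    taken = 0
    if width <= 0:
        return 0
    if rescore:
        while taken < width and state.residual_norm >= eps_abs:
            if _select_one(state, candidates) is None:
                break
            taken += 1
    else:
        cand = np.fromiter(sorted(candidates), dtype=np.intp, count=len(candidates))
        try:
            scores = ols_scores(state.A, state, cand)
        except DegenerateCandidatesError:
            return 0
        order = np.argsort(-scores, kind="stable")[:width]
        for k in order:
            if scores[k] == -np.inf or state.residual_norm < eps_abs:
                break
            j = int(cand[k])
            aj, tj = state.A[:, j], state.T[:, j]
            den = float(aj @ tj)
            if abs(den) < DEFLATION_FLOOR * np.linalg.norm(aj) * np.linalg.norm(tj):
                continue
            q = (float(aj @ state.residual) / den) * tj
            update_residual(state, q)
            state.support.append(j)
            candidates.discard(j)
            deflate_columns(state, q)
            taken += 1
    return taken


def _finalize(A: np.ndarray, y: np.ndarray, state: GreedyState, K_final: int,
              cfg: SolverConfig, converged: bool,
              history: list[tuple[int, int, float]]) -> Solution:
    n = A.shape[1]
    x = np.zeros(n)
    sup = state.support[: max(0, K_final)] if K_final else list(state.support)
    if sup:
        c, _ = restricted_lsq(A, sup, y)
        x[sup] = c
        if cfg.nonneg:
            np.clip(x, 0.0, None, out=x)
    res = float(np.linalg.norm(y - A @ x))
    return Solution(x_hat=x, support_final=list(sup), residual_norm=res,
                    iterations=state.iter, converged=converged, history=history,
                    support_all=list(state.support))


def _adaptive_ols(A: np.ndarray, y: np.ndarray, graph: NeighborGraph | None,
                  cfg: SolverConfig) -> Solution:
    """Core adaptive-sparsity OLS loop; NASOLS when ``graph`` restricts
    candidates to the support's edge neighborhood, ASOLS when ``graph`` is
    ``None`` (all unselected columns stay candidates)."""
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, n = A.shape
    if len(y) != m:
        raise ValueError(f"A has {m} rows but y has {len(y)} entries")
    if graph is not None and graph.n_nodes != n:
        raise ValueError("neighbor graph size must equal the column count of A")

    eps_abs = cfg.eps * (np.linalg.norm(y) if cfg.eps_mode == "rel" else 1.0)
    cap = min(m, n)
    state = GreedyState.fresh(A, y)
    K, L = cfg.K0, cfg.L0
    state.K_cur, state.L_cur = K, L
    history: list[tuple[int, int, float]] = []
    converged = state.residual_norm < eps_abs

    if not converged:
        # initial support: L0 selections over all columns
        candidates = set(range(n))
        _select_batch(state, candidates, cfg.L0, eps_abs,
                      not cfg.init_single_pass, cap)
        converged = state.residual_norm < eps_abs
        history.append((K, L, state.residual_norm))
        logger.debug("init |S|=%d K=%d L=%d ||r||=%.3e",
                     len(state.support), K, L, state.residual_norm)

    prev_norm = state.residual_norm
    while not converged and state.iter < cfg.max_iter and len(state.support) < cap:
        state.iter += 1
        K, L = update_schedule(K, L, state.iter, cfg.K0, cfg.L0)
        state.K_cur, state.L_cur = K, L
        if graph is not None:
            candidates = neighbor_set(graph, state.support)
        else:
            candidates = set(range(n)) - set(state.support)
        if not candidates:
            break
        taken = _select_batch(state, candidates, L, eps_abs, cfg.rescore, cap)
        history.append((K, L, state.residual_norm))
        logger.debug("iter %d |S|=%d K=%d L=%d ||r||=%.3e",
                     state.iter, len(state.support), K, L, state.residual_norm)
        converged = state.residual_norm < eps_abs
        if taken == 0:
            break
        if not converged and cfg.stall_tol > 0.0 and \
                prev_norm - state.residual_norm < cfg.stall_tol * prev_norm:
            break
        prev_norm = state.residual_norm

    K_final = min(K, len(state.support))
    return _finalize(A, y, state, K_final, cfg, converged, history)


# ---------------------------------------------------------------------------
# public solvers
# ---------------------------------------------------------------------------

def nasols(A: np.ndarray, y: np.ndarray, graph: NeighborGraph,
           cfg: SolverConfig | None = None) -> Solution:
    """Neighbor-based adaptive sparsity OLS.

    The first L0 columns are chosen over the whole mesh; afterwards the
    candidate set is the tetrahedral edge neighborhood N(S_i) of the current
    support, the selection width L_i shrinks and the sparsity target K_i
    grows by the adaptive schedule, and the final estimate is a restricted
    least-squares fit on the first K_final selected columns.
    """
    return _adaptive_ols(A, y, graph, cfg or SolverConfig())


def asols(A: np.ndarray, y: np.ndarray,
          cfg: SolverConfig | None = None) -> Solution:
    """Adaptive sparsity OLS without the neighbor restriction (every
    unselected column remains a candidate).  Identical to ``nasols`` with a
    complete graph."""
    return _adaptive_ols(A, y, None, cfg or SolverConfig())


def ols_fixed(A: np.ndarray, y: np.ndarray, K: int,
              cfg: SolverConfig | None = None) -> Solution:
    """Classical OLS with a fixed, manually chosen sparsity K."""
    cfg = cfg or SolverConfig()
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, n = A.shape
    if not (1 <= K <= n):
        raise ValueError("K must lie in [1, column count]")
    if K > min(m, n):
        warnings.warn("K exceeds the rank bound min(m, n); best-effort solve",
                      RuntimeWarning, stacklevel=2)
    eps_abs = cfg.eps * (np.linalg.norm(y) if cfg.eps_mode == "rel" else 1.0)
    state = GreedyState.fresh(A, y)
    candidates = set(range(n))
    history: list[tuple[int, int, float]] = []
    while len(state.support) < min(K, min(m, n)) and state.residual_norm >= eps_abs:
        if _select_one(state, candidates) is None:
            break
        state.iter += 1
        history.append((K, 1, state.residual_norm))
    converged = state.residual_norm < eps_abs or len(state.support) == K
    return _finalize(A, y, state, len(state.support), cfg, converged, history)


def omp(A: np.ndarray, y: np.ndarray, K: int,
        cfg: SolverConfig | None = None) -> Solution:
    """Orthogonal matching pursuit: per iteration add the column most
    correlated with the residual, then refit by restricted least squares."""
    cfg = cfg or SolverConfig()
    return _mp_family(A, y, K, per_iter=1, cfg=cfg)


def gomp(A: np.ndarray, y: np.ndarray, K: int, N_per_iter: int = 6,
         cfg: SolverConfig | None = None) -> Solution:
    """Generalized OMP: add the ``N_per_iter`` most correlated columns per
    iteration (reduces to OMP at N_per_iter=1)."""
    if N_per_iter < 1:
        raise ValueError("N_per_iter must be >= 1")
    cfg = cfg or SolverConfig()
    return _mp_family(A, y, K, per_iter=N_per_iter, cfg=cfg)


def _mp_family(A: np.ndarray, y: np.ndarray, K: int, per_iter: int,
               cfg: SolverConfig) -> Solution:
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, n = A.shape
    if not (1 <= K <= n):
        raise ValueError("K must lie in [1, column count]")
    eps_abs = cfg.eps * (np.linalg.norm(y) if cfg.eps_mode == "rel" else 1.0)
    support: list[int] = []
    r = y.copy()
    history: list[tuple[int, int, float]] = []
    it = 0
    while len(support) < K and np.linalg.norm(r) >= eps_abs:
        it += 1
        corr = np.abs(A.T @ r)
        corr[support] = -np.inf
        take = min(per_iter, K - len(support))
        picks = np.argsort(-corr, kind="stable")[:take]
        support.extend(int(j) for j in picks)
        c, _ = restricted_lsq(A, support, y)
        r = y - A[:, support] @ c
        history.append((K, take, float(np.linalg.norm(r))))
    x = np.zeros(n)
    if support:
        c, _ = restricted_lsq(A, support, y)
        x[support] = c
        if cfg.nonneg:
            np.clip(x, 0.0, None, out=x)
    res = float(np.linalg.norm(y - A @ x))
    return Solution(x_hat=x, support_final=list(support), residual_norm=res,
                    iterations=it, converged=res < eps_abs or len(support) == K,
                    history=history, support_all=list(support))


def cosamp(A: np.ndarray, y: np.ndarray, K: int,
           cfg: SolverConfig | None = None,
           stagnation_tol: float = 1e-7) -> Solution:
    """Compressive sampling matching pursuit with backtracking.

    Per iteration: identify the 2K columns most correlated with the
    residual, merge with the current support, solve restricted least
    squares, prune to the K largest coefficients, and update the residual.
    Halts on the residual threshold, residual stagnation, or max_iter.
    """
    cfg = cfg or SolverConfig()
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, n = A.shape
    if not (1 <= K <= n):
        raise ValueError("K must lie in [1, column count]")
    eps_abs = cfg.eps * (np.linalg.norm(y) if cfg.eps_mode == "rel" else 1.0)
    support: list[int] = []
    r = y.copy()
    prev_norm = float(np.linalg.norm(r))
    history: list[tuple[int, int, float]] = []
    it = 0
    while np.linalg.norm(r) >= eps_abs and it < cfg.max_iter:
        it += 1
        corr = np.abs(A.T @ r)
        ident = np.argsort(-corr, kind="stable")[: 2 * K]
        merged = sorted(set(support) | set(int(j) for j in ident))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            b, _ = restricted_lsq(A, merged, y)
        keep = np.argsort(-np.abs(b), kind="stable")[:K]
        support = [merged[int(k)] for k in sorted(keep)]
        c, _ = restricted_lsq(A, support, y)
        r = y - A[:, support] @ c
        cur = float(np.linalg.norm(r))
        history.append((K, 2 * K, cur))
        if abs(prev_norm - cur) <= stagnation_tol * max(prev_norm, 1e-300):
            break
        prev_norm = cur
    x = np.zeros(n)
    if support:
        c, _ = restricted_lsq(A, support, y)
        x[support] = c
        if cfg.nonneg:
            np.clip(x, 0.0, None, out=x)
    res = float(np.linalg.norm(y - A @ x))
    return Solution(x_hat=x, support_final=list(support), residual_norm=res,
                    iterations=it, converged=res < eps_abs, history=history,
                    support_all=list(support))
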