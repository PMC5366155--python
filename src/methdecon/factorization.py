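"""Regularized constrained matrix factorization of methylation data.

The model is ``D = T A + E`` with ``D`` the observed m x n beta-value matrix,
``T`` (m x k) the latent methylation component (LMC) profiles constrained to
the unit box, and ``A`` (k x n) per-sample mixture proportions constrained to
the probability simplex column-wise.  The fit minimizes

    ||D - TA||_F^2 + lam * sum_is T_is (1 - T_is)

where the penalty pushes component profiles towards biologically plausible
binary methylation states (a single cell's CpG is methylated or not; a
homogeneous cell population is therefore near-binary).

Optimization alternates two exact convex subproblem solvers:

* ``opt_A``: column-wise simplex-constrained least squares for fixed T;
* ``opt_T``: row-wise box-constrained minimization for fixed A.  The penalty
  is concave in T, so the row problem is a difference-of-convex program; the
  concave-convex procedure (CCP) linearizes the concave part ``-lam T^2`` at
  the current iterate, giving convex quadratic surrogates whose exact
  minimization guarantees monotone descent of the true objective.
"""

from __future__ import annotations

import logging

import numpy as np

from ._solvers import BoxQP, simplex_lsq
from .containers import (
    FactorizationConfig,
    FactorizationResult,
    LMCMatrix,
    MethylationMatrix,
    ProportionMatrix,
)

__all__ = [
    "objective",
    "opt_A",
    "opt_T",
    "factorize",
    "init_random",
]

logger = logging.getLogger(__name__)


def _as_values(x, cls) -> np.ndarray:
    if isinstance(x, (MethylationMatrix, LMCMatrix, ProportionMatrix)):
        return x.values
    arr = np.asarray(x, dtype=float)
    return arr


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def objective_arrays(D: np.ndarray, T: np.ndarray, A: np.ndarray, lam: float) -> float:
    resid = D - T @ A
    rss = float(np.sum(resid * resid))
    pen = float(lam * np.sum(T * (1.0 - T)))
    return rss + pen


def objective(D, T, A, lam: float) -> float:
    """Regularized least-squares criterion ``||D - TA||_F^2 + lam * sum w(T)``
    with ``w(x) = x (1 - x)``."""
    D = _as_values(D, MethylationMatrix)
    T = _as_values(T, LMCMatrix)
    A = _as_values(A, ProportionMatrix)
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if np.isnan(D).any() or np.isnan(T).any() or np.isnan(A).any():
        raise ValueError("inputs contain NaN")
    m, n = D.shape
    if T.shape[0] != m or A.shape[1] != n or T.shape[1] != A.shape[0]:
        raise ValueError(
            f"non-conforming shapes: D {D.shape}, T {T.shape}, A {A.shape}"
        )
    return objective_arrays(D, T, A, lam)


# ---------------------------------------------------------------------------
# subproblem: proportions
# ---------------------------------------------------------------------------

def opt_A_arrays(D: np.ndarray, T: np.ndarray, *, inequality: bool = False) -> np.ndarray:
    return simplex_lsq(T, D, inequality=inequality)


def opt_A(D, T, mode: str = "equality") -> ProportionMatrix:
    """Exact column-wise proportion estimates for fixed profiles T.

    Each sample column of A minimizes ``||D_:,j - T a||^2`` over the
    probability simplex (``mode='equality'``) or the sub-simplex with
    ``sum(a) <= 1`` (``mode='inequality'``); columns are independent.
    """
    Dv = _as_values(D, MethylationMatrix)
    Tv = _as_values(T, LMCMatrix)
    if np.isnan(Tv).any():
        raise ValueError("T contains NaN")
    if np.isnan(Dv).any():
        raise ValueError("D contains NaN")
    if mode not in ("equality", "inequality"):
        raise ValueError("mode must be 'equality' or 'inequality'")
    if Dv.shape[0] != Tv.shape[0]:
        raise ValueError(f"shape mismatch: D {Dv.shape}, T {Tv.shape}")
    A = opt_A_arrays(Dv, Tv, inequality=(mode == "inequality"))
    lmc_ids = T.lmc_ids if isinstance(T, LMCMatrix) else None
    sample_ids = D.sample_ids if isinstance(D, MethylationMatrix) else None
    return ProportionMatrix(
        A, lmc_ids=lmc_ids, sample_ids=sample_ids, inequality=(mode == "inequality")
    )


# ---------------------------------------------------------------------------
# subproblem: profiles (CCP)
# ---------------------------------------------------------------------------

def opt_T_arrays(
    D: np.ndarray,
    A: np.ndarray,
    lam: float,
    T_init: np.ndarray,
    max_ccp_iter: int = 50,
    rel_tol: float = 1e-8,
) -> np.ndarray:
    """CCP loop for the row-decoupled profile subproblem at fixed A.

    Each CCP iteration minimizes, exactly and for all rows at once, the convex
    surrogate ``||D - TA||_F^2 + lam * sum (1 - 2 T_hat) T`` over the unit
    box, which never increases the true (penalized, concave-in-T) objective.
    """
    G = A @ A.T  # shared row Hessian / 2
    H = D @ A.T  # (m, k) row linear data terms
    solver = BoxQP(G, 0.0, 1.0)
    T = np.clip(np.asarray(T_init, dtype=float), 0.0, 1.0).copy()
    prev = objective_arrays(D, T, A, lam)
    for _ in range(max_ccp_iter):
        C = -2.0 * H + lam * (1.0 - 2.0 * T)
        T = solver.solve(C)
        cur = objective_arrays(D, T, A, lam)
        if prev - cur <= rel_tol * max(abs(prev), 1.0):
            break
        prev = cur
    return T


def opt_T(
    D,
    A,
    lam: float,
    T_init,
    max_ccp_iter: int = 50,
    rel_tol: float = 1e-8,
) -> LMCMatrix:
    """Box-constrained profile update for fixed proportions A via CCP."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    Dv = _as_values(D, MethylationMatrix)
    Av = _as_values(A, ProportionMatrix)
    Tv = _as_values(T_init, LMCMatrix)
    if Tv.min() < -1e-9 or Tv.max() > 1.0 + 1e-9:
        raise ValueError("T_init must have entries in [0, 1]")
    T = opt_T_arrays(Dv, Av, lam, Tv, max_ccp_iter=max_ccp_iter, rel_tol=rel_tol)
    cpg_ids = D.cpg_ids if isinstance(D, MethylationMatrix) else None
    lmc_ids = A.lmc_ids if isinstance(A, ProportionMatrix) else None
    return LMCMatrix(T, cpg_ids=cpg_ids, lmc_ids=lmc_ids)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_random_arrays(
    m: int, k: int, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    T0 = rng.uniform(0.0, 1.0, size=(m, k))
    A0 = rng.dirichlet(np.ones(k), size=n).T  # columns on the simplex
    A0 /= A0.sum(axis=0, keepdims=True)
    return T0, A0


def init_random(m: int, k: int, n: int, seed: int) -> tuple[LMCMatrix, ProportionMatrix]:
    """Random starting point: T uniform on [0,1], A columns flat-Dirichlet."""
    if m < 1 or k < 1 or n < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    T0, A0 = init_random_arrays(m, k, n, rng)
    return LMCMatrix(T0), ProportionMatrix(A0)


# ---------------------------------------------------------------------------
# alternating minimization
# ---------------------------------------------------------------------------

def factorize_arrays(
    D: np.ndarray,
    k: int,
    lam: float,
    *,
    max_outer_iter: int = 100,
    max_ccp_iter: int = 50,
    rel_tol: float = 1e-8,
    inequality: bool = False,
    seed: int = 0,
    T_init: np.ndarray | None = None,
    A_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Array-level alternating minimization; returns (T, A, trace, converged)."""
    m, n = D.shape
    if T_init is None or A_init is None:
        rng = np.random.default_rng(seed)
        T0, A0 = init_random_arrays(m, k, n, rng)
        if T_init is None:
            T_init = T0
        if A_init is None:
            A_init = A0
    T = np.clip(np.asarray(T_init, dtype=float), 0.0, 1.0).copy()
    A = np.asarray(A_init, dtype=float).copy()

    trace = [objective_arrays(D, T, A, lam)]
    converged = False
    for it in range(max_outer_iter):
        A = opt_A_arrays(D, T, inequality=inequality)
        T = opt_T_arrays(D, A, lam, T, max_ccp_iter=max_ccp_iter, rel_tol=rel_tol)
        cur = objective_arrays(D, T, A, lam)
        trace.append(cur)
        logger.info("outer iteration %d: objective %.8g", it + 1, cur)
        if trace[-2] - cur <= rel_tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
    # final exact proportion refit against the final profiles
    A = opt_A_arrays(D, T, inequality=inequality)
    trace.append(objective_arrays(D, T, A, lam))
    return T, A, trace, converged


def factorize(
    D,
    config: FactorizationConfig,
    T_init=None,
    A_init=None,
) -> FactorizationResult:
    """Alternating minimization of the regularized factorization objective.

    Alternates exact proportion updates (``opt_A``) and CCP profile updates
    (``opt_T``) until the relative objective change falls below
    ``config.rel_tol`` or ``config.max_outer_iter`` is reached.  The recorded
    objective trace is non-increasing.  Non-convergence is reported via
    ``result.converged``, not raised.
    """
    Dv = _as_values(D, MethylationMatrix)
    m, n = Dv.shape
    if config.k > min(m, n):
        raise ValueError(f"k={config.k} exceeds min(m, n)={min(m, n)}")
    inequality = config.constraint_mode == "inequality"
    Ti = _as_values(T_init, LMCMatrix) if T_init is not None else None
    Ai = _as_values(A_init, ProportionMatrix) if A_init is not None else None
    T, A, trace, converged = factorize_arrays(
        Dv,
        config.k,
        config.lam,
        max_outer_iter=config.max_outer_iter,
        max_ccp_iter=config.max_ccp_iter,
        rel_tol=config.rel_tol,
        inequality=inequality,
        seed=config.seed,
        T_init=Ti,
        A_init=Ai,
    )
    resid = Dv - T @ A
    rss = float(np.sum(resid * resid))
    penalty = float(config.lam * np.sum(T * (1.0 - T)))
    cpg_ids = D.cpg_ids if isinstance(D, MethylationMatrix) else None
    sample_ids = D.sample_ids if isinstance(D, MethylationMatrix) else None
    return FactorizationResult(
        T=LMCMatrix(T, cpg_ids=cpg_ids),
        A=ProportionMatrix(A, sample_ids=sample_ids, inequality=inequality),
        objective_trace=trace,
        rss=rss,
        penalty=penalty,
        converged=converged,
        config=config,
    )


def factorize_restarts(
    D,
    config: FactorizationConfig,
    n_restarts: int,
    extra_inits: list[np.ndarray] | None = None,
) -> FactorizationResult:
    """Best-of-restarts factorization.

    Runs ``n_restarts`` random initializations (seeds derived from
    ``config.seed``) plus optional warm-start profile matrices, and returns
    the run with the lowest final objective.
    """
    Dv = _as_values(D, MethylationMatrix)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(max(n_restarts, 0))
    best: FactorizationResult | None = None
    for child in children:
        seed = int(child.generate_state(1)[0] % (2**31))
        cfg = FactorizationConfig(
            k=config.k,
            lam=config.lam,
            max_outer_iter=config.max_outer_iter,
            max_ccp_iter=config.max_ccp_iter,
            rel_tol=config.rel_tol,
            constraint_mode=config.constraint_mode,
            seed=seed,
        )
        res = factorize(D, cfg)
        if best is None or res.objective < best.objective:
            best = res
    for T_warm in extra_inits or []:
        if T_warm.shape != (Dv.shape[0], config.k):
            continue
        A_warm = opt_A_arrays(
            Dv, T_warm, inequality=(config.constraint_mode == "inequality")
        )
        res = factorize(D, config, T_init=T_warm, A_init=A_warm)
        if best is None or res.objective < best.objective:
            best = res
    if best is None:
        raise ValueError("n_restarts must be >= 1 or extra_inits non-empty")
    return best
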