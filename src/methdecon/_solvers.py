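"""Exact solvers for the small constrained quadratic subproblems.

Both alternating-minimization subproblems reduce to many independent convex
quadratic programs sharing a single (small) Hessian:

* proportions: for each sample column ``d``, minimize ``||T a - d||^2`` over
  the probability simplex (or the sub-simplex ``a >= 0, sum(a) <= 1``);
* profiles: for each CpG row ``t``, minimize ``t' G t + c' t`` over the box
  ``[0, 1]^k`` (the CCP surrogate of the regularized row objective).

Because the number of components ``k`` is small (single digits in practice),
each program is solved *exactly* by enumerating active-set patterns: the
optimal active set is one of the ``2^k`` (simplex) or ``3^k`` (box) sign
patterns, each pattern yields a linear system shared across all columns/rows,
and the best feasible candidate is the global minimizer of the convex program.
This is vectorized over thousands of rows at once and deterministic, with no
iterative QP solver involved.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["simplex_lsq", "box_qp", "BoxQP"]

# feasibility slack for candidate solutions
_FEAS_TOL = 1e-9

# enumeration limits; beyond these the pattern count explodes and a generic
# solver would be needed (k above 12 components is outside the method's
# intended regime)
_MAX_K_SIMPLEX = 12
_MAX_K_BOX = 8


def _solve_shared(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve ``M x = rhs`` for a small shared matrix and many right-hand sides,
    falling back to least squares when ``M`` is singular (degenerate inputs,
    e.g. duplicated profile columns)."""
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(M, rhs, rcond=None)[0]


def simplex_lsq(T: np.ndarray, D: np.ndarray, *, inequality: bool = False) -> np.ndarray:
    """Minimize ``||T a_j - D[:, j]||^2`` for every column ``j``.

    Parameters
    ----------
    T
        ``(m, k)`` design matrix (component profiles).
    D
        ``(m, n)`` targets, one column per independent program.
    inequality
        If False, constrain each ``a_j`` to the probability simplex
        (``a >= 0``, ``sum(a) = 1``); if True, to the sub-simplex
        (``a >= 0``, ``sum(a) <= 1``).

    Returns
    -------
    ``(k, n)`` array of exact minimizers.
    """
    T = np.asarray(T, dtype=float)
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    m, k = T.shape
    if D.shape[0] != m:
        raise ValueError(f"shape mismatch: T is {T.shape}, D is {D.shape}")

    if inequality:
        # slack component with an all-zero profile turns sum(a) <= 1 into an
        # equality problem in k + 1 variables
        T_aug = np.hstack([T, np.zeros((m, 1))])
        A = simplex_lsq(T_aug, D, inequality=False)
        return A[:k, :]

    if k > _MAX_K_SIMPLEX:
        raise ValueError(
            f"k={k} exceeds the active-set enumeration limit ({_MAX_K_SIMPLEX})"
        )

    n = D.shape[1]
    G = T.T @ T  # (k, k)
    H = T.T @ D  # (k, n)

    best_obj = np.full(n, np.inf)
    best_a = np.zeros((k, n))

    for r in range(1, k + 1):
        for free in itertools.combinations(range(k), r):
            F = list(free)
            # KKT system for the equality-constrained subproblem on F:
            # [G_FF  1] [a_F]   [H_F]
            # [1^T   0] [nu ] = [ 1 ]
            M = np.zeros((r + 1, r + 1))
            M[:r, :r] = G[np.ix_(F, F)]
            M[:r, r] = 1.0
            M[r, :r] = 1.0
            rhs = np.vstack([H[F, :], np.ones((1, n))])
            sol = _solve_shared(M, rhs)
            a_F = sol[:r, :]

            feas = np.all(a_F >= -_FEAS_TOL, axis=0)
            # equality constraint may be violated when M is singular and the
            # lstsq fallback was taken
            feas &= np.abs(a_F.sum(axis=0) - 1.0) <= 1e-7
            if not feas.any():
                continue

            # objective (up to the constant ||d||^2): a'Ga - 2 a'H
            GA = G[np.ix_(range(k), F)] @ a_F  # (k, n)
            obj = np.einsum("in,in->n", a_F, GA[F, :]) - 2.0 * np.einsum(
                "in,in->n", a_F, H[F, :]
            )
            better = feas & (obj < best_obj - 1e-15)
            if better.any():
                best_obj[better] = obj[better]
                a_full = np.zeros((k, better.sum()))
                a_full[F, :] = a_F[:, better]
                best_a[:, better] = a_full

    # numerical cleanup: clip tiny negatives, renormalize tiny sum deviations
    best_a = np.clip(best_a, 0.0, None)
    s = best_a.sum(axis=0)
    fix = np.abs(s - 1.0) < 1e-6
    best_a[:, fix] /= s[fix]
    return best_a


class BoxQP:
    """Batch solver for ``min_t t' G t + c' t`` over the box ``[lo, hi]^k``.

    The shared PSD Hessian ``G`` is fixed at construction so the per-pattern
    sub-matrices and their (pseudo-)inverses are computed once and reused
    across repeated :meth:`solve` calls — the CCP inner loop solves this
    problem many times with the same ``G`` and a changing linear term.
    """

    def __init__(self, G: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> None:
        G = np.asarray(G, dtype=float)
        k = G.shape[0]
        if G.shape != (k, k):
            raise ValueError("G must be square")
        if k > _MAX_K_BOX:
            raise ValueError(f"k={k} exceeds the box enumeration limit ({_MAX_K_BOX})")
        self.G = G
        self.k = k
        self.lo = lo
        self.hi = hi
        # Precompute pattern metadata, grouped by number of free coordinates
        # so that solve() runs a handful of batched operations per group
        # instead of a Python loop over all 3^k patterns.
        # Pattern code per coordinate: 0=lo, 1=hi, 2=free.
        groups: dict[int, list] = {}
        for pattern in itertools.product((0, 1, 2), repeat=k):
            F = np.array([i for i, p in enumerate(pattern) if p == 2], dtype=int)
            B = np.array([i for i, p in enumerate(pattern) if p != 2], dtype=int)
            fixed = np.array([lo if p == 0 else hi for p in pattern if p != 2])
            if F.size:
                G_FF = G[np.ix_(F, F)]
                try:
                    inv = np.linalg.inv(G_FF)
                except np.linalg.LinAlgError:
                    inv = np.linalg.pinv(G_FF)
                offset = G[np.ix_(F, B)] @ fixed if B.size else np.zeros(F.size)
            else:
                inv = np.zeros((0, 0))
                offset = np.zeros(0)
            base = np.zeros(k)
            if B.size:
                base[B] = fixed
            groups.setdefault(F.size, []).append((F, base, inv, offset))

        self._groups = []
        for f, items in sorted(groups.items()):
            F_stack = np.array([it[0] for it in items], dtype=int)  # (P, f)
            base_stack = np.array([it[1] for it in items])  # (P, k)
            inv_stack = np.array([it[2] for it in items])  # (P, f, f)
            off_stack = np.array([it[3] for it in items])  # (P, f)
            self._groups.append((f, F_stack, base_stack, inv_stack, off_stack))

    def solve(self, C: np.ndarray) -> np.ndarray:
        """Exact minimizers for every row of the ``(m, k)`` linear-term matrix."""
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[None, :]
        if C.shape[1] != self.k:
            raise ValueError(f"shape mismatch: G is {self.G.shape}, C is {C.shape}")
        m = C.shape[0]
        G, lo, hi, k = self.G, self.lo, self.hi, self.k
        best_obj = np.full(m, np.inf)
        best_t = np.zeros((m, k))
        for f, F_stack, base_stack, inv_stack, off_stack in self._groups:
            P = F_stack.shape[0]
            if f == 0:
                # pure vertex candidates: objective via two matmuls
                V = base_stack  # (P, k)
                quad = ((V @ G) * V).sum(axis=1)  # (P,)
                obj = quad[None, :] + C @ V.T  # (m, P)
                t_full = np.broadcast_to(V, (m, P, k))
                feas_obj = obj
            else:
                # stationarity on free coords: G_FF t_F = -(c_F/2 + G_FB t_B)
                rhs = C[:, F_stack] * -0.5 - off_stack[None, :, :]  # (m, P, f)
                t_F = np.einsum("mpf,pfg->mpg", rhs, inv_stack)
                feas = ((t_F >= lo - _FEAS_TOL) & (t_F <= hi + _FEAS_TOL)).all(axis=2)
                t_full = np.broadcast_to(base_stack, (m, P, k)).copy()
                rowsel = np.arange(P)[:, None]
                t_full[:, rowsel, F_stack] = np.clip(t_F, lo, hi)
                tG = t_full @ G  # (m, P, k)
                obj = (tG * t_full).sum(axis=2) + (t_full * C[:, None, :]).sum(axis=2)
                feas_obj = np.where(feas, obj, np.inf)
            idx = feas_obj.argmin(axis=1)
            cand_obj = feas_obj[np.arange(m), idx]
            better = cand_obj < best_obj - 1e-15
            if better.any():
                best_obj[better] = cand_obj[better]
                best_t[better] = t_full[np.arange(m), idx][better]
        return best_t


def box_qp(G: np.ndarray, C: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """One-shot form of :class:`BoxQP` for a single linear-term batch."""
    return BoxQP(G, lo, hi).solve(C)
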