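"""Recovery metrics and the unregularized sub-simplex baseline.

``evaluate_recovery`` scores a factorization against known ground truth (or
reference profiles) by first matching estimated to true components through
the mutual-maximum correlation rule, completing unmatched components
greedily by best remaining correlation (optionally by Hungarian assignment),
then reporting the root-mean-square error over the matched profile entries
and the mean absolute error over the matched proportion entries.

``run_baseline_reffree`` reproduces the behavior of unregularized
deconvolution with the relaxed column-sum constraint (proportions summing to
at most one): it fits on the most variable CpGs and re-estimates profiles on
all CpGs as a final step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import (
    FactorizationConfig,
    FactorizationResult,
    LMCMatrix,
    MethylationMatrix,
    ProportionMatrix,
)
from .factorization import factorize_restarts, opt_T_arrays
from .interpret import _cross_correlation, select_most_variable

__all__ = ["RecoveryMetrics", "evaluate_recovery", "match_components", "run_baseline_reffree"]


@dataclass
class RecoveryMetrics:
    rmse_T: float
    mae_A: float | None
    assignment: list  # (estimated_index, true_index)
    n_mutual: int


def match_components(
    T_hat: np.ndarray, T_true: np.ndarray, *, hungarian: bool = False
) -> tuple[list, int]:
    """One-to-one assignment of estimated to true component columns.

    Mutual-maximum correlation pairs are fixed first; remaining components
    are completed greedily by the best remaining correlation (or, with
    ``hungarian=True``, by maximum-total-correlation assignment over all
    components at once).  Returns pairs over min(k, k_true) components and
    the number of mutual matches.
    """
    S = _cross_correlation(T_hat, T_true, center=True)
    S = np.where(np.isnan(S), -np.inf, S)
    k, k_true = S.shape
    n_pairs = min(k, k_true)

    if hungarian:
        rows, cols = linear_sum_assignment(-S)
        pairs = list(zip(rows.tolist(), cols.tolist()))[:n_pairs]
        mutual = sum(
            1
            for i, j in pairs
            if S[i, j] == S[:, j].max() and S[i, j] == S[i, :].max()
        )
        return pairs, mutual

    pairs = []
    used_i, used_j = set(), set()
    for j in range(k_true):
        i = int(S[:, j].argmax())
        if S[i, j] == S[i, :].max() and i not in used_i and j not in used_j:
            pairs.append((i, j))
            used_i.add(i)
            used_j.add(j)
    n_mutual = len(pairs)
    while len(pairs) < n_pairs:
        best, arg = -np.inf, None
        for i in range(k):
            if i in used_i:
                continue
            for j in range(k_true):
                if j in used_j:
                    continue
                if S[i, j] > best:
                    best, arg = S[i, j], (i, j)
        if arg is None:
            break
        pairs.append(arg)
        used_i.add(arg[0])
        used_j.add(arg[1])
    return pairs, n_mutual


def evaluate_recovery(
    result: FactorizationResult | tuple,
    T_true: LMCMatrix | np.ndarray,
    A_true: ProportionMatrix | np.ndarray | None = None,
    *,
    top_cpgs: int | None = None,
    hungarian: bool = False,
) -> RecoveryMetrics:
    """Score estimated profiles/proportions against ground truth.

    ``top_cpgs`` restricts the profile RMSE to the CpGs with the largest
    variance across the true profiles (where the deconvolution signal lives).
    A k mismatch is scored over the min(k, k_true) matched components.
    """
    if isinstance(result, FactorizationResult):
        T_hat = result.T.values
        A_hat = result.A.values
    else:
        T_hat, A_hat = result
        T_hat = T_hat.values if isinstance(T_hat, LMCMatrix) else np.asarray(T_hat)
        A_hat = A_hat.values if isinstance(A_hat, ProportionMatrix) else (
            np.asarray(A_hat) if A_hat is not None else None
        )
    T_t = T_true.values if isinstance(T_true, LMCMatrix) else np.asarray(T_true)
    A_t = A_true.values if isinstance(A_true, ProportionMatrix) else (
        np.asarray(A_true) if A_true is not None else None
    )
    if T_hat.shape[0] != T_t.shape[0]:
        raise ValueError("profile matrices must share their CpG rows")

    pairs, n_mutual = match_components(T_hat, T_t, hungarian=hungarian)
    if not pairs:
        raise ValueError("no components could be matched")

    rows = np.arange(T_t.shape[0])
    if top_cpgs is not None and top_cpgs < T_t.shape[0]:
        var = T_t.var(axis=1)
        rows = np.sort(np.argsort(-var, kind="stable")[:top_cpgs])

    est_idx = [i for i, _ in pairs]
    tru_idx = [j for _, j in pairs]
    diff_T = T_hat[np.ix_(rows, est_idx)] - T_t[np.ix_(rows, tru_idx)]
    rmse_T = float(np.sqrt(np.mean(diff_T**2)))

    mae_A = None
    if A_hat is not None and A_t is not None:
        diff_A = A_hat[est_idx, :] - A_t[tru_idx, :]
        mae_A = float(np.mean(np.abs(diff_A)))
    return RecoveryMetrics(rmse_T=rmse_T, mae_A=mae_A, assignment=pairs, n_mutual=n_mutual)


def run_baseline_reffree(
    D: MethylationMatrix,
    k: int,
    n_restarts: int = 1,
    seed: int = 0,
    *,
    n_variable: int = 20000,
    max_outer_iter: int = 100,
    rel_tol: float = 1e-8,
) -> FactorizationResult:
    """Unregularized sub-simplex baseline deconvolution.

    Factorizes with lambda = 0 and the inequality column-sum constraint on
    the ``n_variable`` most variable CpGs (or all CpGs if fewer), then
    re-estimates the full profile matrix against the fitted proportions as a
    final step.
    """
    if not isinstance(D, MethylationMatrix):
        D = MethylationMatrix(np.asarray(D, dtype=float))
    D_sub = select_most_variable(D, min(n_variable, D.shape[0]))
    cfg = FactorizationConfig(
        k=k,
        lam=0.0,
        constraint_mode="inequality",
        seed=seed,
        max_outer_iter=max_outer_iter,
        rel_tol=rel_tol,
    )
    fit = factorize_restarts(D_sub, cfg, n_restarts)
    # final step: profiles for every CpG given the fitted proportions
    T_full = opt_T_arrays(D.values, fit.A.values, 0.0, np.full((D.shape[0], k), 0.5),
                          max_ccp_iter=1)
    resid = D.values - T_full @ fit.A.values
    return FactorizationResult(
        T=LMCMatrix(T_full, cpg_ids=D.cpg_ids),
        A=ProportionMatrix(fit.A.values, sample_ids=D.sample_ids, inequality=True),
        objective_trace=fit.objective_trace,
        rss=float(np.sum(resid * resid)),
        penalty=0.0,
        converged=fit.converged,
        config=cfg,
    )
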