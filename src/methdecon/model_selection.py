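"""Model selection for the factorization: cross-validation over (k, lambda).

The number of components k and the regularization weight lambda are selected
by column-leave-out cross-validation: samples (columns of D) are partitioned
into folds; for each fold the remaining columns are factorized as usual, the
held-out columns are then fit against the trained profiles by
simplex-constrained least squares, and the held-out squared reconstruction
error (CVE) is accumulated.  Lambda is searched on a two-stage grid (coarse,
then a finer log-spaced grid around the coarse minimum).  Because the
factorization is non-convex, every grid cell is fit from multiple random
restarts, complemented by a smoothing scheme that warm-starts each cell from
the solutions of neighboring lambda grid points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import FactorizationConfig, FactorizationResult, MethylationMatrix
from .factorization import (
    _as_values,
    factorize_restarts,
    opt_A_arrays,
)

__all__ = ["CVConfig", "CVResult", "cv_error", "grid_search", "select_model"]

logger = logging.getLogger(__name__)

#: coarse lambda grid default; brackets the useful regularization range for
#: beta-value data (0 disables the penalty; 0.1 is already strongly binary)
DEFAULT_LAMBDA_GRID = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)


@dataclass
class CVConfig:
    """Settings for the (k, lambda) cross-validated grid search."""

    ks: Sequence[int] = (2, 3, 4, 5)
    lambda_grid_coarse: Sequence[float] = DEFAULT_LAMBDA_GRID
    fine_grid_size: int = 8
    n_folds: int = 10
    n_restarts: int = 50
    neighbor_window: int = 5
    seed: int = 0
    # factorization controls for the per-fold and full-data fits
    max_outer_iter: int = 100
    max_ccp_iter: int = 50
    rel_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")
        lams = list(self.lambda_grid_coarse)
        if not lams or not list(self.ks):
            raise ValueError("empty (k, lambda) grid")
        if any(l < 0 for l in lams):
            raise ValueError("lambda values must be non-negative")
        if sorted(lams) != lams:
            raise ValueError("lambda grid must be sorted ascending")
        if any(k < 1 for k in self.ks):
            raise ValueError("k values must be positive")


@dataclass
class CVResult:
    """CVE surface and fitted models from :func:`grid_search`."""

    cve: pd.DataFrame  # long format: k, lam, cve, rss_in, stage
    best_fit: dict  # (k, lam) -> FactorizationResult on the full data
    selected_k: int
    selected_lambda: float

    def cve_table(self) -> pd.DataFrame:
        """CVE pivoted to a k x lambda table."""
        return self.cve.pivot_table(index="k", columns="lam", values="cve")


def _fold_assignment(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF01D)))
    perm = rng.permutation(n)
    return [np.sort(perm[f::n_folds]) for f in range(n_folds)]


def _cell_seed(seed: int, k: int, lam_key: int) -> int:
    ss = np.random.SeedSequence((seed, k, lam_key))
    return int(ss.generate_state(1)[0] % (2**31))


def cv_error(
    D,
    k: int,
    lam: float,
    n_folds: int = 10,
    n_restarts: int = 1,
    seed: int = 0,
    *,
    warm_starts: list[np.ndarray] | None = None,
    max_outer_iter: int = 100,
    max_ccp_iter: int = 50,
    rel_tol: float = 1e-8,
) -> float:
    """Column-leave-out cross-validation error for one (k, lambda) cell.

    Partitions samples into ``n_folds`` disjoint folds by a seeded shuffle.
    For each fold, the remaining columns are factorized (best of
    ``n_restarts`` random restarts plus optional profile warm starts, judged
    by the in-sample objective), the held-out columns are fit against the
    trained profiles by plain simplex-constrained least squares (the penalty
    does not enter the held-out fit), and the squared error is accumulated.
    Returns the mean squared error per held-out matrix entry.
    """
    Dv = _as_values(D, MethylationMatrix)
    m, n = Dv.shape
    if n < n_folds:
        raise ValueError(f"n_folds={n_folds} exceeds the number of samples {n}")
    folds = _fold_assignment(n, n_folds, seed)
    sse = 0.0
    for f, idx_out in enumerate(folds):
        idx_in = np.setdiff1d(np.arange(n), idx_out)
        if idx_in.size < k:
            raise ValueError(
                f"fold {f} leaves only {idx_in.size} training samples for k={k}; "
                "use fewer folds or a smaller k"
            )
        cfg = FactorizationConfig(
            k=k,
            lam=lam,
            seed=_cell_seed(seed, k, f),
            max_outer_iter=max_outer_iter,
            max_ccp_iter=max_ccp_iter,
            rel_tol=rel_tol,
        )
        fit = factorize_restarts(Dv[:, idx_in], cfg, n_restarts, extra_inits=warm_starts)
        T_in = fit.T.values
        A_out = opt_A_arrays(Dv[:, idx_out], T_in)
        resid = Dv[:, idx_out] - T_in @ A_out
        sse += float(np.sum(resid * resid))
    return sse / (m * n)


def _full_data_fit(
    Dv: np.ndarray,
    k: int,
    lam: float,
    config: CVConfig,
    lam_key: int,
    warm_starts: list[np.ndarray],
) -> FactorizationResult:
    cfg = FactorizationConfig(
        k=k,
        lam=lam,
        seed=_cell_seed(config.seed, k, lam_key),
        max_outer_iter=config.max_outer_iter,
        max_ccp_iter=config.max_ccp_iter,
        rel_tol=config.rel_tol,
    )
    return factorize_restarts(Dv, cfg, config.n_restarts, extra_inits=warm_starts)


def _sweep_lambdas(
    Dv: np.ndarray,
    k: int,
    lams: Sequence[float],
    config: CVConfig,
    lam_key_offset: int,
    records: list[dict],
    best_fit: dict,
    stage: int,
) -> None:
    """Evaluate one k over a lambda grid, with neighbor-smoothing warm starts.

    An ascending pass fits each cell from random restarts plus the profile
    solutions of up to ``neighbor_window`` preceding grid points; a descending
    refinement pass then offers each cell the solutions of its following
    neighbors and keeps whichever fit has the lower in-sample objective.  The
    CVE for each cell reuses the full-data solutions of the cell and its
    neighbors as fold warm starts.
    """
    w = config.neighbor_window
    fits: list[FactorizationResult] = []
    for j, lam in enumerate(lams):
        warm = [f.T.values for f in fits[max(0, j - w) : j]]
        fits.append(_full_data_fit(Dv, k, lam, config, lam_key_offset + j, warm))
    # descending pass: propagate solutions from following grid points
    for j in range(len(lams) - 2, -1, -1):
        warm = [fits[t].T.values for t in range(j + 1, min(len(lams), j + 1 + w))]
        refit = factorize_restarts(
            Dv,
            FactorizationConfig(
                k=k,
                lam=lams[j],
                seed=_cell_seed(config.seed, k, lam_key_offset + j),
                max_outer_iter=config.max_outer_iter,
                max_ccp_iter=config.max_ccp_iter,
                rel_tol=config.rel_tol,
            ),
            0,
            extra_inits=warm,
        ) if warm else None
        if refit is not None and refit.objective < fits[j].objective:
            fits[j] = refit

    for j, lam in enumerate(lams):
        neighbors = range(max(0, j - w), min(len(lams), j + 1 + w))
        warm = [fits[t].T.values for t in neighbors]
        cve = cv_error(
            Dv,
            k,
            lam,
            n_folds=config.n_folds,
            n_restarts=config.n_restarts,
            seed=_cell_seed(config.seed, k, lam_key_offset + j),
            warm_starts=warm,
            max_outer_iter=config.max_outer_iter,
            max_ccp_iter=config.max_ccp_iter,
            rel_tol=config.rel_tol,
        )
        logger.info("CV cell k=%d lambda=%g: cve=%.6g rss=%.6g", k, lam, cve, fits[j].rss)
        records.append(
            {"k": k, "lam": lam, "cve": cve, "rss_in": fits[j].rss, "stage": stage}
        )
        best_fit[(k, lam)] = fits[j]


def grid_search(D, config: CVConfig) -> CVResult:
    """Two-stage (k, lambda) grid search by cross-validation.

    Stage 1 evaluates the CVE over ``ks x lambda_grid_coarse``.  Stage 2
    builds a finer, log-spaced lambda grid spanning the two coarse grid
    points bracketing the stage-1 argmin (for the argmin k) and repeats.
    Returns the full CVE table and the grid argmin.
    """
    Dv = _as_values(D, MethylationMatrix)
    records: list[dict] = []
    best_fit: dict = {}

    lams = [float(l) for l in config.lambda_grid_coarse]
    for k in config.ks:
        _sweep_lambdas(Dv, k, lams, config, 0, records, best_fit, stage=1)

    df = pd.DataFrame.from_records(records)
    i_min = df["cve"].idxmin()
    k_star = int(df.loc[i_min, "k"])
    lam_star = float(df.loc[i_min, "lam"])

    if config.fine_grid_size > 0 and len(lams) > 1:
        j = lams.index(lam_star)
        lo = lams[max(0, j - 1)]
        hi = lams[min(len(lams) - 1, j + 1)]
        if lo <= 0.0:
            # log spacing cannot reach zero; span two decades below the upper
            # bracket and keep the zero cell from stage 1 for comparison
            lo = hi / 100.0 if hi > 0 else 1e-6
        if hi <= lo:
            hi, lo = max(hi, lo), min(hi, lo)
        if hi > lo:
            fine = np.geomspace(lo, hi, config.fine_grid_size)
            fine = sorted(set(float(x) for x in fine) - set(lams))
            if fine:
                _sweep_lambdas(
                    Dv, k_star, fine, config, 1000, records, best_fit, stage=2
                )
                df = pd.DataFrame.from_records(records)

    i_min = df["cve"].idxmin()
    return CVResult(
        cve=df.sort_values(["k", "lam"]).reset_index(drop=True),
        best_fit=best_fit,
        selected_k=int(df.loc[i_min, "k"]),
        selected_lambda=float(df.loc[i_min, "lam"]),
    )


def select_model(result: CVResult, flat_tolerance: float = 0.01) -> tuple[int, float]:
    """Pick (k, lambda) from a CVE surface with a flatness rule.

    The CVE-vs-k curve typically levels out once k reaches the true number of
    components; the default rule returns the smallest k whose best-over-lambda
    CVE is within ``flat_tolerance`` (relative) of the global minimum,
    together with that k's argmin lambda.  This automates the visual
    inspection a user would otherwise perform on the emitted CVE table.
    """
    df = result.cve
    per_k = df.groupby("k")["cve"].min()
    global_min = per_k.min()
    for k in sorted(per_k.index):
        if per_k[k] <= global_min * (1.0 + flat_tolerance):
            sub = df[df["k"] == k]
            lam = float(sub.loc[sub["cve"].idxmin(), "lam"])
            return int(k), lam
    raise AssertionError("unreachable: global minimum k always satisfies the rule")
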