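"""Phenotype association analysis with cell-composition adjustment.

Epigenome-wide association scans on heterogeneous tissue are confounded by
cell composition: if the phenotype shifts the mixing proportions, every CpG
whose methylation differs between cell types shows a spurious association.
This module provides the per-CpG association test (logistic for binary
phenotypes, ordinary least squares for numeric ones), residualization of the
methylation matrix on technical/demographic covariates, selection of the k'
largest-proportion latent components as adjustment covariates, and a Q-Q /
genomic-inflation diagnostic of the resulting p-value distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import MethylationMatrix, ProportionMatrix

__all__ = [
    "AssociationResult",
    "residualize",
    "top_k_lmcs",
    "association_test",
    "qq_inflation",
]

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    table: pd.DataFrame  # per CpG: beta, stat, p_value, direction
    adjustment: str
    lambda_gc: float
    qq_points: pd.DataFrame  # expected vs observed -log10 p, sorted
    n_failed: int = 0

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Build a full-rank design matrix (with intercept) from a covariate table,
    dummy-encoding non-numeric columns."""
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    enc = pd.get_dummies(covariates, drop_first=True).astype(float)
    X = np.column_stack([np.ones(n), enc.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        cols = [np.ones(n)]
        for name, col in zip(enc.columns, enc.to_numpy().T):
            trial = np.column_stack(cols + [col])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                bad.append(str(name))
            else:
                cols.append(col)
        raise ValueError(f"collinear covariate column(s): {bad}")
    return X


def residualize(
    D: MethylationMatrix | np.ndarray, covariate_table: pd.DataFrame | None
) -> pd.DataFrame:
    """Per-CpG OLS residuals of methylation on covariates (with intercept).

    With no covariates this reduces to centering each CpG.  The residual
    matrix (CpGs x samples, no longer bounded to [0, 1]) is returned as a
    DataFrame and can be passed to :func:`association_test` in place of raw
    beta values for the two-stage adjusted analysis.
    """
    values = D.values if isinstance(D, MethylationMatrix) else np.asarray(D, float)
    n = values.shape[1]
    X = _design(covariate_table, n)
    # projection residual: D (I - X (X'X)^-1 X')
    coef, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    resid = values - (X @ coef).T
    if isinstance(D, MethylationMatrix):
        return pd.DataFrame(resid, index=D.cpg_ids, columns=D.sample_ids)
    return pd.DataFrame(resid)


def top_k_lmcs(A: ProportionMatrix, k_prime: int) -> np.ndarray:
    """Indices of the k' components with the largest mean proportions, descending."""
    if k_prime > A.shape[0]:
        raise ValueError(f"k_prime={k_prime} exceeds k={A.shape[0]}")
    means = A.values.mean(axis=1)
    return np.argsort(-means, kind="stable")[:k_prime]


def _is_simplex_complete(Z: np.ndarray) -> bool:
    return Z.shape[1] > 1 and np.allclose(Z.sum(axis=1), 1.0, atol=1e-6)


def association_test(
    D: MethylationMatrix | pd.DataFrame | np.ndarray,
    phenotype,
    extra_covariates: np.ndarray | pd.DataFrame | None = None,
    family: str = "binary",
    *,
    max_iter: int = 100,
) -> AssociationResult:
    """Per-CpG association scan of a phenotype against methylation.

    For each CpG fits ``phenotype ~ methylation + extra covariates`` —
    logistic regression for ``family='binary'``, OLS for ``family='numeric'``
    — and reports the Wald test of the methylation coefficient.  When the
    extra covariates are a complete set of simplex proportions (rows summing
    to one per sample), the last one is dropped to avoid collinearity with
    the intercept.  Per-CpG convergence failures yield missing p-values and
    are counted, not raised.
    """
    if isinstance(D, MethylationMatrix):
        values, cpg_ids = D.values, list(D.cpg_ids)
    elif isinstance(D, pd.DataFrame):
        values, cpg_ids = D.to_numpy(dtype=float), [str(i) for i in D.index]
    else:
        values = np.asarray(D, dtype=float)
        cpg_ids = [f"cpg{i + 1}" for i in range(values.shape[0])]
    y = np.asarray(phenotype, dtype=float)
    n = values.shape[1]
    if y.shape[0] != n:
        raise ValueError("phenotype length must match the number of samples")
    if np.unique(y).size < 2:
        raise ValueError("phenotype is constant")
    if family not in ("binary", "numeric"):
        raise ValueError("family must be 'binary' or 'numeric'")
    if family == "binary" and np.unique(y).size != 2:
        raise ValueError("binary family requires exactly two classes")

    if extra_covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(
            extra_covariates.to_numpy()
            if isinstance(extra_covariates, pd.DataFrame)
            else extra_covariates,
            dtype=float,
        )
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError("extra covariates must have one row per sample")
        if _is_simplex_complete(Z):
            Z = Z[:, :-1]

    m = values.shape[0]
    betas = np.full(m, np.nan)
    ps = np.full(m, np.nan)
    zs = np.full(m, np.nan)
    n_failed = 0
    base = np.column_stack([np.ones(n), np.zeros(n), Z])
    for i in range(m):
        base[:, 1] = values[i]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if family == "binary":
                    fit = sm.Logit(y, base).fit(disp=False, maxiter=max_iter)
                    if not fit.mle_retvals.get("converged", True):
                        raise np.linalg.LinAlgError("no convergence")
                else:
                    fit = sm.OLS(y, base).fit()
            betas[i] = fit.params[1]
            zs[i] = fit.tvalues[1]
            ps[i] = fit.pvalues[1]
            if not np.isfinite(ps[i]):
                raise np.linalg.LinAlgError("non-finite p")
        except Exception:
            n_failed += 1
    if n_failed:
        logger.warning("association_test: %d of %d CpG fits failed", n_failed, m)

    # statsmodels can return p == 0 by underflow; keep p in (0, 1]
    ps = np.where(np.isfinite(ps), np.clip(ps, 1e-300, 1.0), np.nan)
    table = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "beta": betas,
            "stat": zs,
            "p_value": ps,
            "direction": np.sign(betas),
        }
    )
    ok = table["p_value"].dropna().to_numpy()
    lam_gc, qq = qq_inflation(ok) if ok.size >= 10 else (np.nan, pd.DataFrame())
    adj = "none" if Z.shape[1] == 0 else f"{Z.shape[1]} covariate(s)"
    return AssociationResult(
        table=table, adjustment=adj, lambda_gc=lam_gc, qq_points=qq, n_failed=n_failed
    )


def qq_inflation(p_values) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and Q-Q points for a set of p-values.

    ``lambda_gc`` is the median chi-square(1) quantile of the observed
    p-values divided by the null median (0.4549...); the Q-Q table pairs the
    sorted observed -log10 p with uniform order-statistic expectations.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 10:
        raise ValueError("at least 10 p-values are required")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    lambda_gc = float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
    obs = np.sort(p)
    expected = (np.arange(1, p.size + 1) - 0.5) / p.size
    qq = pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(obs),
        }
    ).sort_values("expected_neglog10", ignore_index=True)
    return lambda_gc, qq
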