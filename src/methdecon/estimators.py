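"""scikit-learn compatible estimators.

These wrap the factorization and model-selection machinery in the
fit/transform idiom so they compose with sklearn pipelines and model
selection.  Following sklearn's orientation, ``X`` is samples x features
(n samples x m CpGs), i.e. the transpose of the field's CpG x sample
matrices; ``components_`` holds the latent methylation component profiles as
rows and ``transform`` returns per-sample mixture proportions on the
probability simplex.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import FactorizationConfig
from .factorization import factorize_restarts, opt_A_arrays
from .model_selection import CVConfig, grid_search, select_model

__all__ = ["MethylationDeconvolution", "DeconvolutionCV"]


class MethylationDeconvolution(TransformerMixin, BaseEstimator):
    """Regularized simplex-constrained deconvolution of methylation profiles.

    Decomposes beta-value profiles into ``n_components`` latent methylation
    components (cell-type-like prototype methylomes with entries in [0, 1])
    and per-sample mixture proportions on the probability simplex.  The
    ``alpha`` penalty ``alpha * sum T (1 - T)`` biases component profiles
    towards binary methylation states.

    Parameters
    ----------
    n_components : int
        Number of latent components k.
    alpha : float
        Weight of the binary-promoting penalty (the factorization's lambda).
    constraint : {'equality', 'inequality'}
        Whether per-sample proportions sum to exactly one or at most one.
    n_restarts : int
        Random restarts; the fit with the lowest objective is kept.
    max_outer_iter, max_ccp_iter, tol
        Optimization controls of the alternating scheme.
    random_state : int
        Seed for the random initializations.

    Attributes
    ----------
    components_ : ndarray of shape (n_components, n_features)
        Latent component profiles (rows; entries in [0, 1]).
    proportions_ : ndarray of shape (n_samples, n_components)
        Mixture proportions of the training samples.
    objective_trace_ : list of float
        Non-increasing objective values of the alternating scheme.
    rss_, penalty_, converged_, n_iter_
        Final fit diagnostics.
    """

    def __init__(
        self,
        n_components: int = 2,
        alpha: float = 0.0,
        constraint: str = "equality",
        n_restarts: int = 1,
        max_outer_iter: int = 100,
        max_ccp_iter: int = 50,
        tol: float = 1e-8,
        random_state: int = 0,
    ) -> None:
        self.n_components = n_components
        self.alpha = alpha
        self.constraint = constraint
        self.n_restarts = n_restarts
        self.max_outer_iter = max_outer_iter
        self.max_ccp_iter = max_ccp_iter
        self.tol = tol
        self.random_state = random_state

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x CpGs)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("beta values must lie in [0, 1]")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        cfg = FactorizationConfig(
            k=self.n_components,
            lam=self.alpha,
            max_outer_iter=self.max_outer_iter,
            max_ccp_iter=self.max_ccp_iter,
            rel_tol=self.tol,
            constraint_mode=self.constraint,
            seed=self.random_state,
        )
        res = factorize_restarts(X.T, cfg, self.n_restarts)
        self.components_ = res.T.values.T
        self.proportions_ = res.A.values.T
        self.objective_trace_ = res.objective_trace
        self.rss_ = res.rss
        self.penalty_ = res.penalty
        self.converged_ = res.converged
        self.n_iter_ = len(res.objective_trace) - 1
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Proportions of the fitted components in new samples."""
        check_is_fitted(self, "components_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        A = opt_A_arrays(
            X.T, self.components_.T, inequality=(self.constraint == "inequality")
        )
        return A.T

    def inverse_transform(self, P) -> np.ndarray:
        check_is_fitted(self, "components_")
        return np.asarray(P, dtype=float) @ self.components_


class DeconvolutionCV(BaseEstimator):
    """Cross-validated selection of (n_components, alpha) for deconvolution.

    Runs the two-stage column-leave-out cross-validated grid search and
    exposes a fitted :class:`MethylationDeconvolution` at the selected cell.
    """

    def __init__(
        self,
        ks=(2, 3, 4, 5),
        alphas=(0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1),
        n_folds: int = 10,
        n_restarts: int = 10,
        fine_grid_size: int = 0,
        flat_tolerance: float = 0.01,
        max_outer_iter: int = 100,
        tol: float = 1e-8,
        random_state: int = 0,
    ) -> None:
        self.ks = ks
        self.alphas = alphas
        self.n_folds = n_folds
        self.n_restarts = n_restarts
        self.fine_grid_size = fine_grid_size
        self.flat_tolerance = flat_tolerance
        self.max_outer_iter = max_outer_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        cfg = CVConfig(
            ks=tuple(self.ks),
            lambda_grid_coarse=tuple(self.alphas),
            fine_grid_size=self.fine_grid_size,
            n_folds=self.n_folds,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            max_outer_iter=self.max_outer_iter,
            rel_tol=self.tol,
        )
        res = grid_search(X.T, cfg)
        self.cv_result_ = res
        self.cve_ = res.cve
        k, lam = select_model(res, self.flat_tolerance)
        self.selected_k_ = k
        self.selected_alpha_ = lam
        fit = res.best_fit[(k, lam)]
        est = MethylationDeconvolution(
            n_components=k,
            alpha=lam,
            n_restarts=self.n_restarts,
            max_outer_iter=self.max_outer_iter,
            tol=self.tol,
            random_state=self.random_state,
        )
        est.components_ = fit.T.values.T
        est.proportions_ = fit.A.values.T
        est.objective_trace_ = fit.objective_trace
        est.rss_ = fit.rss
        est.penalty_ = fit.penalty
        est.converged_ = fit.converged
        est.n_iter_ = len(fit.objective_trace) - 1
        est.n_features_in_ = X.shape[1]
        self.best_estimator_ = est
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.transform(X)
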