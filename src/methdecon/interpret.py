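"""Interpretation of fitted components.

Covers matching of estimated latent methylation components (LMCs) against
reference profiles (e.g. purified cell-type methylomes) via a Pearson
correlation matrix with mutual-maximum matching and a normalized matching
score, combined hierarchical clustering of estimated and reference profiles,
selection of component-specific CpG positions by a methylation-difference
threshold, reference-based proportion estimation, and discriminative /
most-variable CpG preselection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway

from .containers import LMCMatrix, MethylationMatrix, ProportionMatrix
from .factorization import opt_A

__all__ = [
    "MatchResult",
    "SpecificCpGSet",
    "match_lmcs",
    "cluster_lmcs",
    "lmc_specific_cpgs",
    "pairwise_specific_cpgs",
    "reference_proportions",
    "select_most_variable",
    "select_discriminative_cpgs",
]


@dataclass
class MatchResult:
    """Correlation matching between estimated and reference components.

    ``epsilon`` is the number of unambiguous (mutual-maximum) matches
    normalized by min(k, k*), hence in [0, 1] with 1 meaning a perfect
    one-to-one correspondence.
    """

    S: np.ndarray  # k x k* Pearson correlations
    pairs: list  # (lmc_index, ref_index) mutual-maximum matches
    ambiguous: list  # column-maximum matches that are not mutual
    epsilon: float
    centered: bool
    ties: list = field(default_factory=list)


@dataclass
class SpecificCpGSet:
    lmc_index: int
    theta: float
    cpg_ids: list
    deltas: np.ndarray


def _shared_rows(T_hat: LMCMatrix, T_ref: LMCMatrix) -> tuple[np.ndarray, np.ndarray]:
    shared = [c for c in T_hat.cpg_ids if c in set(T_ref.cpg_ids)]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} probes shared between the two profile sets; "
            "correlation matching needs at least 3"
        )
    ix_hat = {c: i for i, c in enumerate(T_hat.cpg_ids)}
    ix_ref = {c: i for i, c in enumerate(T_ref.cpg_ids)}
    rows_hat = np.array([ix_hat[c] for c in shared])
    rows_ref = np.array([ix_ref[c] for c in shared])
    return T_hat.values[rows_hat, :], T_ref.values[rows_ref, :]


def _cross_correlation(X: np.ndarray, Y: np.ndarray, center: bool) -> np.ndarray:
    """Pearson correlations between all column pairs of X and Y.

    If ``center``, each matrix first has its per-row mean across its own
    columns subtracted from every column (so correlations measure agreement
    of deviations from the matrix's average profile).  Zero-variance columns
    yield NaN correlations.
    """
    if center:
        X = X - X.mean(axis=1, keepdims=True)
        Y = Y - Y.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt((Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        S = (Xc.T @ Yc) / np.outer(sx, sy)
    S[:, sy == 0] = np.nan
    S[sx == 0, :] = np.nan
    return S


def match_lmcs(T_hat: LMCMatrix, T_ref: LMCMatrix, center: bool = True) -> MatchResult:
    """Match estimated components to reference profiles by Pearson correlation.

    A component i-bar matches reference j-bar when S[i-bar, j-bar] is the
    maximum of column j-bar; the match is unambiguous (mutual) when it is
    also the maximum of row i-bar.  Ties are broken towards the lowest index
    and recorded.
    """
    X, Y = _shared_rows(T_hat, T_ref)
    S = _cross_correlation(X, Y, center)
    k, k_star = S.shape
    if np.isnan(S).any():
        bad = sorted(
            set(np.where(np.isnan(S).all(axis=1))[0].tolist())
            | set(np.where(np.isnan(S).all(axis=0))[0].tolist())
        )
        warnings.warn(
            f"zero-variance profile column(s) {bad}: correlations undefined, "
            "excluded from matching"
        )
    S_safe = np.where(np.isnan(S), -np.inf, S)

    pairs, ambiguous, ties = [], [], []
    for j in range(k_star):
        col = S_safe[:, j]
        if not np.isfinite(col).any():
            continue
        i = int(col.argmax())  # argmax breaks ties towards the lowest index
        if (col == col[i]).sum() > 1:
            ties.append((i, j))
        row = S_safe[i, :]
        if row[j] == row.max():
            pairs.append((i, j))
        else:
            ambiguous.append((i, j))
    epsilon = len(pairs) / min(k, k_star)
    return MatchResult(
        S=S, pairs=pairs, ambiguous=ambiguous, epsilon=epsilon, centered=center, ties=ties
    )


def cluster_lmcs(T_hat: LMCMatrix, T_ref: LMCMatrix) -> np.ndarray:
    """Average-linkage clustering of estimated and reference profiles.

    Concatenates both profile sets on their shared probes, computes the
    column-wise Pearson correlation matrix, converts it to the distance
    ``1 - r``, and returns the scipy linkage matrix over the k + k* columns
    (leaves ordered as [estimated..., reference...]).
    """
    X, Y = _shared_rows(T_hat, T_ref)
    J = np.hstack([X, Y])
    S = _cross_correlation(J, J, center=False)
    if np.isnan(S).any():
        raise ValueError("zero-variance column: correlation distance undefined")
    Dist = 1.0 - S
    np.fill_diagonal(Dist, 0.0)
    Dist = np.clip((Dist + Dist.T) / 2.0, 0.0, None)
    return linkage(squareform(Dist, checks=False), method="average")


def _deltas(T: np.ndarray, i: int, literal_sum: bool) -> np.ndarray:
    others = np.delete(T, i, axis=1)
    if literal_sum:
        return T[:, i] - others.sum(axis=1)
    return T[:, i] - others.mean(axis=1)


def lmc_specific_cpgs(
    T_hat: LMCMatrix,
    lmc_index: int,
    theta: float = 0.33,
    *,
    literal_sum: bool = False,
) -> SpecificCpGSet:
    """CpGs specific to one component.

    A CpG is specific to component ``i`` when its methylation there differs
    from the mean over the other components by more than ``theta`` in
    absolute value.  ``literal_sum=True`` switches to comparing against the
    plain sum of the other components instead of their mean (an alternative
    reading of the selection rule; note the sum scales with k).  Output is
    sorted by |delta| descending.
    """
    if not 0.0 < theta < 1.0 and not literal_sum:
        raise ValueError("theta must lie in (0, 1)")
    if T_hat.k < 2:
        raise ValueError("component-specific CpGs require k >= 2")
    if not 0 <= lmc_index < T_hat.k:
        raise ValueError(f"component index {lmc_index} out of range")
    d = _deltas(T_hat.values, lmc_index, literal_sum)
    sel = np.abs(d) > theta
    idx = np.where(sel)[0]
    order = idx[np.argsort(-np.abs(d[idx]), kind="stable")]
    return SpecificCpGSet(
        lmc_index=lmc_index,
        theta=theta,
        cpg_ids=[T_hat.cpg_ids[i] for i in order],
        deltas=d[order],
    )


def pairwise_specific_cpgs(
    T_hat: LMCMatrix, i: int, j: int, theta: float = 0.33
) -> SpecificCpGSet:
    """CpGs with methylation difference above ``theta`` between components i, j."""
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    if i == j:
        raise ValueError("component indices must differ")
    d = T_hat.values[:, i] - T_hat.values[:, j]
    sel = np.abs(d) > theta
    idx = np.where(sel)[0]
    order = idx[np.argsort(-np.abs(d[idx]), kind="stable")]
    return SpecificCpGSet(
        lmc_index=i,
        theta=theta,
        cpg_ids=[T_hat.cpg_ids[t] for t in order],
        deltas=d[order],
    )


def reference_proportions(D: MethylationMatrix, T_ref: LMCMatrix) -> ProportionMatrix:
    """Reference-based proportion estimation ("regression").

    Restricts both matrices to their shared probes and solves the
    simplex-constrained least-squares proportion problem against the
    reference profiles.
    """
    shared = [c for c in D.cpg_ids if c in set(T_ref.cpg_ids)]
    if len(shared) < T_ref.k:
        raise ValueError(
            f"{len(shared)} shared probes but k={T_ref.k} references; need at least k"
        )
    ix_d = {c: i for i, c in enumerate(D.cpg_ids)}
    ix_r = {c: i for i, c in enumerate(T_ref.cpg_ids)}
    D_sub = MethylationMatrix(
        D.values[[ix_d[c] for c in shared], :], cpg_ids=shared, sample_ids=D.sample_ids
    )
    T_sub = LMCMatrix(
        T_ref.values[[ix_r[c] for c in shared], :], cpg_ids=shared, lmc_ids=T_ref.lmc_ids
    )
    return opt_A(D_sub, T_sub, mode="equality")


def select_most_variable(D: MethylationMatrix, count: int) -> MethylationMatrix:
    """Keep the ``count`` CpG rows with the largest across-sample variance.

    Survivors keep their original row order; variance ties are broken by
    probe ID.
    """
    if count > D.shape[0]:
        raise ValueError(f"count={count} exceeds m={D.shape[0]}")
    var = D.values.var(axis=1, ddof=1)
    order = sorted(range(len(var)), key=lambda i: (-var[i], D.cpg_ids[i]))
    keep = np.sort(np.array(order[:count]))
    return MethylationMatrix(
        D.values[keep, :],
        cpg_ids=[D.cpg_ids[i] for i in keep],
        sample_ids=D.sample_ids,
    )


def select_discriminative_cpgs(
    D: MethylationMatrix, group_labels, count: int
) -> MethylationMatrix:
    """Keep the ``count`` CpGs with the highest one-way ANOVA F across groups.

    Intended for marker selection on labeled (e.g. purified cell-type)
    samples.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != D.shape[1]:
        raise ValueError("one group label per sample is required")
    groups = [np.where(labels == g)[0] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 samples")
    if count > D.shape[0]:
        raise ValueError(f"count={count} exceeds m={D.shape[0]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        F, _ = f_oneway(*(D.values[:, g] for g in groups), axis=1)
    # constant rows: F undefined -> 0; zero within-group variance: F = inf,
    # which legitimately ranks first
    F = np.where(np.isnan(F), 0.0, F)
    order = np.argsort(-F, kind="stable")
    keep = np.sort(order[:count])
    return MethylationMatrix(
        D.values[keep, :],
        cpg_ids=[D.cpg_ids[i] for i in keep],
        sample_ids=D.sample_ids,
    )
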