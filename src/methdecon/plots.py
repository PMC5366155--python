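"""Static diagnostic plots: CVE surface, component dendrogram, Q-Q plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering; callers save to file

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

__all__ = ["plot_cve", "plot_dendrogram", "plot_qq"]


def plot_cve(cve_table, ax=None):
    """CVE versus lambda, one line per candidate k (log-x, linear-y)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for k, sub in cve_table.groupby("k"):
        sub = sub.sort_values("lam")
        lam = sub["lam"].to_numpy()
        # show the lambda = 0 cell at a pseudo-position one decade below the
        # smallest positive grid point
        positive = lam[lam > 0]
        x = np.where(lam > 0, lam, (positive.min() / 10 if positive.size else 1e-6))
        ax.plot(x, sub["cve"], marker="o", label=f"k={k}")
    ax.set_xscale("log")
    ax.set_xlabel("lambda")
    ax.set_ylabel("cross-validation error")
    ax.legend(fontsize=8)
    return ax


def plot_dendrogram(linkage_matrix, labels, ax=None):
    """Average-linkage tree of estimated and reference components."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    dendrogram(linkage_matrix, labels=list(labels), ax=ax, leaf_rotation=90)
    ax.set_ylabel("1 - Pearson correlation")
    return ax


def plot_qq(qq_points, lambda_gc=None, ax=None):
    """Observed versus expected -log10 p with the identity reference line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x = qq_points["expected_neglog10"]
    y = qq_points["observed_neglog10"]
    ax.scatter(x, y, s=6)
    lim = max(float(x.max()), float(y.max()))
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    label = "expected -log10 p"
    if lambda_gc is not None:
        ax.set_title(f"genomic inflation = {lambda_gc:.2f}")
    ax.set_xlabel(label)
    ax.set_ylabel("observed -log10 p")
    return ax
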