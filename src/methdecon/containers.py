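"""Domain containers: labeled matrices and factorization configuration/results.

All matrices follow the field convention of CpGs (probes) on rows and samples
on columns; component (LMC) profile matrices are CpGs x components and
proportion matrices components x samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "LMCMatrix",
    "ProportionMatrix",
    "FactorizationConfig",
    "FactorizationResult",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {dups[:5]}")
    return ids


@dataclass
class MethylationMatrix:
    """Observed beta-value matrix D (m CpGs x n samples), entries in [0, 1]."""

    values: np.ndarray
    cpg_ids: Sequence[str] | None = None
    sample_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("methylation matrix must be 2-dimensional")
        m, n = self.values.shape
        if self.cpg_ids is None:
            self.cpg_ids = [f"cpg{i + 1}" for i in range(m)]
        if self.sample_ids is None:
            self.sample_ids = [f"sample{j + 1}" for j in range(n)]
        self.cpg_ids = _check_unique(self.cpg_ids, "probe IDs")
        self.sample_ids = _check_unique(self.sample_ids, "sample IDs")
        if len(self.cpg_ids) != m or len(self.sample_ids) != n:
            raise ValueError("ID lengths do not match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("methylation matrix contains non-finite values")
        if self.values.min() < -1e-9 or self.values.max() > 1.0 + 1e-9:
            raise ValueError("beta values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)


@dataclass
class LMCMatrix:
    """Latent methylation component profiles T (m CpGs x k components).

    Also used for reference profiles (e.g. purified cell-type methylomes).
    """

    values: np.ndarray
    cpg_ids: Sequence[str] | None = None
    lmc_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("component matrix must be 2-dimensional")
        m, k = self.values.shape
        if self.cpg_ids is None:
            self.cpg_ids = [f"cpg{i + 1}" for i in range(m)]
        if self.lmc_ids is None:
            self.lmc_ids = [f"LMC{s + 1}" for s in range(k)]
        self.cpg_ids = _check_unique(self.cpg_ids, "probe IDs")
        self.lmc_ids = _check_unique(self.lmc_ids, "component IDs")
        if len(self.cpg_ids) != m or len(self.lmc_ids) != k:
            raise ValueError("ID lengths do not match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("component matrix contains non-finite values")
        if self.values.min() < -1e-9 or self.values.max() > 1.0 + 1e-9:
            raise ValueError("component profile values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.lmc_ids)


@dataclass
class ProportionMatrix:
    """Mixture proportions A (k components x n samples).

    Columns lie on the probability simplex (equality mode) or the sub-simplex
    with column sums at most one (inequality / baseline mode).
    """

    values: np.ndarray
    lmc_ids: Sequence[str] | None = None
    sample_ids: Sequence[str] | None = None
    inequality: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("proportion matrix must be 2-dimensional")
        k, n = self.values.shape
        if self.lmc_ids is None:
            self.lmc_ids = [f"LMC{s + 1}" for s in range(k)]
        if self.sample_ids is None:
            self.sample_ids = [f"sample{j + 1}" for j in range(n)]
        self.lmc_ids = _check_unique(self.lmc_ids, "component IDs")
        self.sample_ids = _check_unique(self.sample_ids, "sample IDs")
        if len(self.lmc_ids) != k or len(self.sample_ids) != n:
            raise ValueError("ID lengths do not match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("proportion matrix contains non-finite values")
        if self.values.min() < -1e-9:
            raise ValueError("proportions must be non-negative")
        sums = self.values.sum(axis=0)
        if self.inequality:
            if sums.max() > 1.0 + 1e-6:
                raise ValueError("column sums must not exceed 1 in inequality mode")
        else:
            if np.abs(sums - 1.0).max() > 1e-6:
                raise ValueError("columns must sum to 1 in equality mode")
        self.values = np.clip(self.values, 0.0, None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lmc_ids, columns=self.sample_ids)


@dataclass
class FactorizationConfig:
    """Settings for one factorization run.

    ``lam`` weights the binary-promoting penalty sum of T_is (1 - T_is);
    ``constraint_mode`` selects the simplex ("equality") or sub-simplex
    ("inequality") constraint on proportion columns.
    """

    k: int = 2
    lam: float = 0.0
    max_outer_iter: int = 100
    max_ccp_iter: int = 50
    rel_tol: float = 1e-8
    constraint_mode: str = "equality"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.lam < 0:
            raise ValueError("regularization weight must be non-negative")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.max_outer_iter < 1 or self.max_ccp_iter < 1:
            raise ValueError("iteration limits must be positive")
        if self.constraint_mode not in ("equality", "inequality"):
            raise ValueError("constraint_mode must be 'equality' or 'inequality'")


@dataclass
class FactorizationResult:
    T: LMCMatrix
    A: ProportionMatrix
    objective_trace: list = field(default_factory=list)
    rss: float = np.nan
    penalty: float = np.nan
    converged: bool = False
    config: FactorizationConfig | None = None

    @property
    def objective(self) -> float:
        return self.rss + self.penalty
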