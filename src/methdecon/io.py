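"""Reading and writing of matrices, configurations, and run metadata.

The canonical on-disk format is TSV with probe IDs in a first column headed
``cpg_id`` and one column per sample; CSV is accepted on read (delimiter
auto-detected).  Values are beta fractions; rows containing missing or
out-of-range values are rejected with a count report rather than imputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LMCMatrix, MethylationMatrix, ProportionMatrix

__all__ = [
    "read_beta_matrix",
    "write_matrix",
    "read_lmc_matrix",
    "read_proportion_matrix",
    "write_fit_json",
    "write_run_json",
]

logger = logging.getLogger(__name__)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate probe IDs: {dups}")
    return df


def read_beta_matrix(path) -> MethylationMatrix:
    """Read a beta-value matrix, dropping (and counting) invalid rows.

    Rows containing missing values or values outside [0, 1] are rejected;
    the number of rejected rows is logged and available from the returned
    matrix as ``n_rejected_rows``.
    """
    df = _read_table(path)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    ok = np.isfinite(values).all(axis=1) & (values >= 0).all(axis=1) & (values <= 1).all(axis=1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d row(s) with missing or out-of-range values",
            path,
            n_rejected,
        )
    if ok.sum() == 0:
        raise ValueError(f"{path}: no valid rows")
    if values.shape[1] > 100 and values.shape[0] < values.shape[1]:
        # arrays measure orders of magnitude more CpGs than samples
        logger.warning(
            "%s: more columns (%d) than rows (%d) — is the matrix transposed "
            "(expected CpGs x samples)?",
            path, values.shape[1], values.shape[0],
        )
    mat = MethylationMatrix(
        values[ok, :],
        cpg_ids=[str(i) for i in df.index[ok]],
        sample_ids=[str(c) for c in df.columns],
    )
    mat.n_rejected_rows = n_rejected
    return mat


def read_lmc_matrix(path) -> LMCMatrix:
    df = _read_table(path)
    return LMCMatrix(
        df.to_numpy(dtype=float),
        cpg_ids=[str(i) for i in df.index],
        lmc_ids=[str(c) for c in df.columns],
    )


def read_proportion_matrix(path, inequality: bool = False) -> ProportionMatrix:
    df = _read_table(path)
    return ProportionMatrix(
        df.to_numpy(dtype=float),
        lmc_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        inequality=inequality,
    )


def write_matrix(obj, path, index_label: str = "cpg_id") -> None:
    """Write a labeled matrix as TSV (dot decimal, no quoting)."""
    if isinstance(obj, ProportionMatrix):
        index_label = "lmc"
    obj.to_frame().to_csv(path, sep="\t", index_label=index_label)


def write_fit_json(result, path) -> None:
    cfg = result.config
    payload = {
        "objective_trace": [float(x) for x in result.objective_trace],
        "rss": result.rss,
        "penalty": result.penalty,
        "converged": bool(result.converged),
        "config": None
        if cfg is None
        else {
            "k": cfg.k,
            "lam": cfg.lam,
            "max_outer_iter": cfg.max_outer_iter,
            "max_ccp_iter": cfg.max_ccp_iter,
            "rel_tol": cfg.rel_tol,
            "constraint_mode": cfg.constraint_mode,
            "seed": cfg.seed,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_json(out_dir, subcommand: str, params: dict, inputs: list) -> None:
    """Record everything needed to reproduce a CLI run."""
    import methdecon

    payload = {
        "subcommand": subcommand,
        "params": {k: (v if not isinstance(v, Path) else str(v)) for k, v in params.items()},
        "inputs": {str(p): _checksum(p) for p in inputs if p and Path(p).exists()},
        "versions": {
            "methdecon": methdecon.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(out_dir, "run.json").write_text(json.dumps(payload, indent=2, default=str))
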