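"""Co-expression ranking by Pearson correlation across conditions.

Correlations are computed on log2(TPM+1) by default: tissue-level TPM spans
orders of magnitude and Pearson on the raw scale is dominated by the few
highest-expressing conditions.  The raw scale remains available via
``log_transform=False``.  Genes whose profile has zero variance have no
defined correlation; they are reported as NaN and excluded from rankings
rather than coerced to zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

COEXPRESSION_COLUMNS = ["gene_id", "pearson_r", "n_conditions", "rank"]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two vectors.

    Requires equal lengths >= 3 and finite input.  Returns NaN (the
    undefined marker) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_r needs 1-d vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("input vectors must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _log_values(expr: ExpressionMatrix, log_transform: bool) -> np.ndarray:
    return np.log2(expr.values + 1.0) if log_transform else expr.values


def top_coexpressed(
    expr: ExpressionMatrix,
    query_gene: str,
    k: int = 500,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Rank all other genes by correlation with ``query_gene``.

    Every gene except the query is correlated against the query's profile
    across conditions; the top ``k`` by r descending are returned with ranks
    1..K (K <= k when fewer genes are available — no padding).  Genes with
    undefined correlation are excluded.  Ties in r break lexicographically
    by gene id, so top-k lists are reproducible.
    """
    if query_gene not in expr.data.index:
        raise KeyError(f"unknown query gene: {query_gene!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if expr.n_conditions < 3:
        raise ValueError("correlation needs at least 3 conditions")

    x = _log_values(expr, log_transform)
    qi = expr.gene_ids.index(query_gene)
    q = x[qi]

    centered = x - x.mean(axis=1, keepdims=True)
    qc = q - q.mean()
    q_ss = qc @ qc
    gene_ss = np.einsum("ij,ij->i", centered, centered)
    denom = np.sqrt(gene_ss * q_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0.0, centered @ qc / np.where(denom == 0, 1, denom), np.nan)
    r = np.clip(r, -1.0, 1.0)

    out = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "pearson_r": r,
            "n_conditions": expr.n_conditions,
        }
    )
    out = out[(out["gene_id"] != query_gene) & out["pearson_r"].notna()]
    out = out.sort_values(
        ["pearson_r", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(k)
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out[COEXPRESSION_COLUMNS]


def locus_correlation(
    expr: ExpressionMatrix,
    gene_set: list[str],
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pairwise correlation matrix for a set of genes (e.g. one locus).

    Returns a symmetric DataFrame with unit diagonal, indexed by
    ``gene_set`` in the given order.  Zero-variance genes yield NaN
    off-diagonal entries.
    """
    unknown = [g for g in gene_set if g not in expr.data.index]
    if unknown:
        raise KeyError(f"unknown gene(s): {unknown}")
    if len(gene_set) < 2:
        raise ValueError("locus correlation needs at least 2 genes")

    x = _log_values(expr, log_transform)
    idx = [expr.gene_ids.index(g) for g in gene_set]
    sub = x[idx]
    centered = sub - sub.mean(axis=1, keepdims=True)
    ss = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    denom = np.outer(ss, ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0.0, centered @ centered.T / np.where(denom == 0, 1, denom), np.nan)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    # enforce exact symmetry against floating-point asymmetry in the matmul
    corr = (corr + corr.T) / 2.0
    return pd.DataFrame(corr, index=gene_set, columns=gene_set)
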