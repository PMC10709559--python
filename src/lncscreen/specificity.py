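"""Tissue-specificity scoring by Z-score difference.

For each gene, expression across tissues is standardized to Z-scores and the
specificity score for a target tissue is

    score = Z(target) - max over t != target of Z(t)

A positive score means the gene is expressed more highly in the target tissue
than in any other tissue; a negative score means at least one other tissue
exceeds it.  For a gene expressed in exactly one of ``n`` tissues the score
under the sample-sd convention has the closed form ``sqrt(n)``, which bounds
how large the score can get.

Candidate selection combines this score with an abundance gate (TPM in the
target tissue) and a differential-expression gate, mirroring how a
regulator-dependent, tissue-restricted transcript is short-listed from a
knock-down contrast plus a tissue atlas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import classify_de
from .io import DEResultTable, ExpressionMatrix

SPECIFICITY_COLUMNS = [
    "gene_id",
    "target_tissue",
    "target_expression",
    "z_target",
    "z_max_other",
    "score",
    "degenerate",
]


def zscore_profile(expr: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, bool]:
    """Standardize one expression vector across tissues.

    Returns ``(z, degenerate)`` where ``z[t] = (x[t] - mean(x)) / sd(x)``
    with sample standard deviation (``ddof=1``) by default.  A zero-variance
    vector is flagged degenerate and maps to all-zero Z rather than NaN, so
    downstream ranking never propagates NaN.
    """
    x = np.asarray(expr, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("zscore_profile needs a 1-d vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("expression vector must be finite")
    if (x < 0).any():
        raise ValueError("expression vector must be non-negative")
    sd = x.std(ddof=ddof)
    if sd == 0.0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def specificity_score(
    expr_matrix: ExpressionMatrix,
    target_tissue: str,
    ddof: int = 1,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Score every gene's restriction to ``target_tissue``.

    Z-scores are computed per gene across tissues, on raw TPM by default
    (``log_transform`` switches to log2(TPM+1) before standardizing;
    ``target_expression`` stays on the TPM scale either way).  Zero-variance
    genes get score 0 with ``degenerate=True``.  Output rows follow the
    input gene order.

    Returns a DataFrame with columns ``gene_id, target_tissue,
    target_expression, z_target, z_max_other, score, degenerate``.
    """
    if target_tissue not in expr_matrix.condition_ids:
        raise KeyError(f"target tissue {target_tissue!r} not in matrix")
    if expr_matrix.n_conditions < 2:
        raise ValueError("specificity needs at least 2 tissues")

    values = expr_matrix.values
    target_idx = expr_matrix.condition_ids.index(target_tissue)
    target_tpm = values[:, target_idx]

    x = np.log2(values + 1.0) if log_transform else values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = sd[:, 0] == 0.0
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[degenerate, :] = 0.0

    z_target = z[:, target_idx]
    others = np.delete(z, target_idx, axis=1)
    z_max_other = others.max(axis=1)
    score = np.where(degenerate, 0.0, z_target - z_max_other)
    z_max_other = np.where(degenerate, 0.0, z_max_other)

    return pd.DataFrame(
        {
            "gene_id": expr_matrix.gene_ids,
            "target_tissue": target_tissue,
            "target_expression": target_tpm,
            "z_target": np.where(degenerate, 0.0, z_target),
            "z_max_other": z_max_other,
            "score": score,
            "degenerate": degenerate,
        }
    )


def select_candidates(
    spec: pd.DataFrame,
    de: DEResultTable,
    min_tpm: float = 10.0,
    min_score: float = 5.0,
    direction: str = "down",
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Gate specificity results on abundance, specificity and DE status.

    A gene is a candidate when it (i) classifies as differentially expressed
    in the requested ``direction`` (``down``, ``up`` or ``any``), (ii) has
    target-tissue expression strictly above ``min_tpm`` TPM and (iii) a
    specificity score strictly above ``min_score``.  Both gates are strict,
    matching the printed ">10 TPM" / ">5" convention.  Candidates are ranked
    by score descending, ties broken by |log2FC| descending then gene id.
    """
    if direction not in {"down", "up", "any"}:
        raise ValueError(f"direction must be down/up/any, got {direction!r}")
    if not (np.isfinite(min_tpm) and np.isfinite(min_score)):
        raise ValueError("thresholds must be finite")

    classes = classify_de(
        de, lfc_threshold=lfc_threshold, p_threshold=p_threshold, use_adjusted=use_adjusted
    )
    merged = spec.merge(classes, on="gene_id", how="inner")
    if direction == "any":
        de_ok = merged["status"].isin(["up", "down"])
    else:
        de_ok = merged["status"] == direction
    keep = de_ok & (merged["target_expression"] > min_tpm) & (merged["score"] > min_score)
    out = merged.loc[keep].copy()
    out["abs_lfc"] = out["log2_fold_change"].abs()
    out = out.sort_values(
        ["score", "abs_lfc", "gene_id"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="abs_lfc")
    return out.reset_index(drop=True)
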