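"""Differential-expression screening of a supplied DE results table.

The classifier applies the conventional volcano gates with strict
inequalities: a gene is called up when log2FC > threshold and p < alpha,
down when log2FC < -threshold and p < alpha, otherwise not significant.
The p-value compared against alpha is the nominal p by default; pass
``use_adjusted=True`` to gate on the BH-adjusted column instead — the
choice changes the up/down counts and is therefore explicit, never guessed.
Genes with a missing p-value classify as not significant (logged), they are
never dropped silently.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import DEResultTable

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NOT_SIGNIFICANT = "not_significant"


def classify_de(
    de: DEResultTable,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Classify every gene as up / down / not_significant.

    Returns a DataFrame with columns ``gene_id, status, log2_fold_change,
    p_used`` in input order.  ``p_used`` is the p-value column actually
    compared against ``p_threshold``.
    """
    if not (lfc_threshold > 0 and p_threshold > 0):
        raise ValueError("thresholds must be positive")
    df = de.data
    if use_adjusted:
        if df["p_adjusted"].isna().any():
            n = int(df["p_adjusted"].isna().sum())
            raise ValueError(
                f"use_adjusted requested but {n} records lack an adjusted p-value"
            )
        p_used = df["p_adjusted"].to_numpy(dtype=float)
    else:
        p_used = df["p_value"].to_numpy(dtype=float)

    lfc = df["log2_fold_change"].to_numpy(dtype=float)
    missing_p = np.isnan(p_used)
    if missing_p.any():
        logger.info(
            "%d genes with missing p-values classified as not_significant",
            int(missing_p.sum()),
        )
    significant = ~missing_p & (p_used < p_threshold)
    status = np.full(len(df), NOT_SIGNIFICANT, dtype=object)
    status[significant & (lfc > lfc_threshold)] = UP
    status[significant & (lfc < -lfc_threshold)] = DOWN

    return pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "status": status,
            "log2_fold_change": lfc,
            "p_used": p_used,
        }
    )


def summarize_counts(classes: pd.DataFrame) -> tuple[int, int]:
    """Return ``(n_down, n_up)`` from a classification table."""
    counts = classes["status"].value_counts()
    return int(counts.get(DOWN, 0)), int(counts.get(UP, 0))
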