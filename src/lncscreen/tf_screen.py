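"""Multi-stage transcription-factor screening funnel.

Given a TF catalogue, a tissue expression matrix, a differentiation time
course and the tissue profile of a query transcript, the funnel keeps TFs
that

  stage 1: are expressed in the target tissue (TPM strictly above a gate)
           AND trend upward over the differentiation course
           (last-vs-first log2 ratio strictly above a gate);
  stage 2: co-express with the query across tissues (Pearson r strictly
           above a gate) AND are specific to the target tissue relative to
           a named set of competing tissues (target Z minus the maximum
           competing Z strictly above a gate).

Stage-2 statistics are only computed for stage-1 survivors; for stage-1
failures they are reported as NaN (not evaluated).  The funnel is monotone:
tightening any single threshold can only shrink the candidate set, and
|catalogue| >= |stage-1 passes| >= |final candidates| always holds.

The screen reuses the same Z-score convention as the specificity module,
restricted to {target} + competing tissues, so one Z definition holds
repo-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coexpression import pearson_r
from .io import DifferentiationSeries, ExpressionMatrix
from .specificity import zscore_profile

logger = logging.getLogger(__name__)

TF_RESULT_COLUMNS = [
    "tf_id",
    "target_tpm",
    "trend_log2fc",
    "stage1_pass",
    "query_r",
    "competing_delta",
    "stage2_pass",
    "final_candidate",
]


@dataclass
class TFScreenConfig:
    """Thresholds for the two funnel stages.

    The catalogue-to-intermediate-to-final counts of a published screen
    constrain but do not determine these gates; the defaults below are the
    package's own documented choices, all strict inequalities.
    """

    min_tissue_tpm: float = 1.0
    trend_min_log2fc: float = 1.0
    min_query_r: float = 0.5
    competing_tissues: list[str] = field(default_factory=list)
    min_competing_delta: float = 1.0

    def validate(self, target_tissue: str) -> None:
        for name in ("min_tissue_tpm", "trend_min_log2fc", "min_query_r", "min_competing_delta"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.competing_tissues:
            raise ValueError("competing_tissues must be non-empty")
        if target_tissue in self.competing_tissues:
            raise ValueError("competing_tissues must exclude the target tissue")


class TFScreenOutcome(NamedTuple):
    """Full screen table plus the catalogue ids that could not be resolved."""

    results: pd.DataFrame
    unresolved_ids: list[str]

    @property
    def candidates(self) -> pd.DataFrame:
        return self.results[self.results["final_candidate"]].reset_index(drop=True)


def differentiation_trend(
    series: DifferentiationSeries,
    tf_id: str,
    pseudocount: float = 1.0,
    method: str = "log_ratio",
) -> float:
    """Expression trend of one gene over the differentiation course.

    ``log_ratio`` (default): log2((last + pc) / (first + pc)) — the simplest
    monotone-respecting summary of a rise from progenitor to differentiated
    cells.  ``rank_corr``: Spearman correlation of expression with time,
    an alternative that weighs every timepoint.
    """
    profile = series.matrix.profile(tf_id)
    if method == "log_ratio":
        return float(np.log2((profile[-1] + pseudocount) / (profile[0] + pseudocount)))
    if method == "rank_corr":
        rho = sps.spearmanr(series.timepoint_days, profile).statistic
        return float(rho) if np.isfinite(rho) else 0.0
    raise ValueError(f"unknown trend method {method!r}")


def screen_tfs(
    tf_ids: Sequence[str],
    tissue_expr: ExpressionMatrix,
    series: DifferentiationSeries,
    query_profile: np.ndarray,
    target_tissue: str,
    config: TFScreenConfig,
    log_transform: bool = True,
    trend_method: str = "log_ratio",
) -> TFScreenOutcome:
    """Run the two-stage funnel over a TF catalogue.

    ``query_profile`` is the query transcript's expression aligned to
    ``tissue_expr.condition_ids``; the stage-2 correlation is computed across
    those tissues on log2(TPM+1) by default.  Catalogue ids missing from
    either matrix are logged and reported in ``unresolved_ids``, not fatal;
    an entirely unresolvable catalogue raises.  Results are sorted by
    query_r descending (not-evaluated last), ties broken by tf id.
    """
    if target_tissue not in tissue_expr.condition_ids:
        raise KeyError(f"target tissue {target_tissue!r} not in tissue matrix")
    config.validate(target_tissue)
    missing_comp = [t for t in config.competing_tissues if t not in tissue_expr.condition_ids]
    if missing_comp:
        raise KeyError(f"competing tissue(s) not in matrix: {missing_comp}")

    query = np.asarray(query_profile, dtype=float)
    if query.shape != (tissue_expr.n_conditions,):
        raise ValueError(
            f"query profile length {query.size} != {tissue_expr.n_conditions} tissues"
        )

    resolved, unresolved = [], []
    series_genes = set(series.gene_ids)
    expr_genes = set(tissue_expr.gene_ids)
    for tf in tf_ids:
        (resolved if tf in series_genes and tf in expr_genes else unresolved).append(tf)
    if unresolved:
        logger.warning("%d catalogue ids unresolved: %s ...", len(unresolved), unresolved[:5])
    if not resolved:
        raise ValueError("no catalogue id resolves against both matrices")

    target_idx = tissue_expr.condition_ids.index(target_tissue)
    restricted = [target_tissue] + list(config.competing_tissues)
    restricted_cols = [tissue_expr.condition_ids.index(t) for t in restricted]
    q_log = np.log2(query + 1.0) if log_transform else query

    rows = []
    for tf in resolved:
        profile = tissue_expr.profile(tf)
        target_tpm = float(profile[target_idx])
        trend = differentiation_trend(series, tf, method=trend_method)
        stage1 = (target_tpm > config.min_tissue_tpm) and (trend > config.trend_min_log2fc)

        query_r = np.nan
        delta = np.nan
        stage2 = False
        if stage1:
            tf_profile = np.log2(profile + 1.0) if log_transform else profile
            query_r = pearson_r(tf_profile, q_log)
            z, degenerate = zscore_profile(profile[restricted_cols])
            delta = 0.0 if degenerate else float(z[0] - z[1:].max())
            stage2 = (
                np.isfinite(query_r)
                and query_r > config.min_query_r
                and delta > config.min_competing_delta
            )
        rows.append(
            {
                "tf_id": tf,
                "target_tpm": target_tpm,
                "trend_log2fc": trend,
                "stage1_pass": stage1,
                "query_r": query_r,
                "competing_delta": delta,
                "stage2_pass": stage2,
                "final_candidate": stage1 and stage2,
            }
        )

    results = pd.DataFrame(rows, columns=TF_RESULT_COLUMNS)
    results = results.sort_values(
        ["query_r", "tf_id"], ascending=[False, True], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return TFScreenOutcome(results, unresolved)


def funnel_counts(outcome: TFScreenOutcome) -> tuple[int, int, int]:
    """Return (catalogue size, stage-1 passes, final candidates)."""
    res = outcome.results
    return (
        len(res) + len(outcome.unresolved_ids),
        int(res["stage1_pass"].sum()),
        int(res["final_candidate"].sum()),
    )
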