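"""Small statistics used around the pipeline: qPCR ddCt and a two-group DE fit.

The qPCR fold change follows the standard relative-quantification scheme:
dCt = Ct(target) - Ct(housekeeping) per measurement, ddCt = dCt(test) -
dCt(reference), fold = 2^(-ddCt).  By default the reference dCt is the mean
over the reference group's measurements, the common practice when biological
replicates are available; a single measurement works too.

``two_group_de`` builds a DE results table from replicate count matrices:
log2FC on pseudocounted group means, a two-sided Welch t-test on log2(x+1)
replicate values, and Benjamini-Hochberg adjustment across genes.  It is a
deliberately simple fit for synthetic or exploratory data, not a
negative-binomial GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import DEResultTable

#: single pseudocount convention for every log-fold-change in the package
PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well-pair: target and housekeeping Ct for a sample."""

    sample_id: str
    target_ct: float
    housekeeping_ct: float
    group: str = "test"  # "reference" or "test"

    def __post_init__(self) -> None:
        for val in (self.target_ct, self.housekeeping_ct):
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"Ct values must be finite and > 0, got {val}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.housekeeping_ct


def _mean_delta_ct(m: QpcrMeasurement | Iterable[QpcrMeasurement]) -> float:
    if isinstance(m, QpcrMeasurement):
        return m.delta_ct
    dcts = [x.delta_ct for x in m]
    if not dcts:
        raise ValueError("empty measurement group")
    return float(np.mean(dcts))


def delta_delta_ct(
    test: QpcrMeasurement | Iterable[QpcrMeasurement],
    reference: QpcrMeasurement | Iterable[QpcrMeasurement],
) -> float:
    """Relative fold change 2^(-ddCt) of test vs reference.

    Either argument may be a single measurement or a group (mean dCt is
    used for groups).  The result is always strictly positive and satisfies
    fold(test, ref) * fold(ref, test) == 1.
    """
    ddct = _mean_delta_ct(test) - _mean_delta_ct(reference)
    return float(2.0 ** (-ddct))


def _as_count_frame(counts, label: str) -> pd.DataFrame:
    df = pd.DataFrame(counts)
    if df.shape[1] < 2:
        raise ValueError(f"{label} needs at least 2 replicates, got {df.shape[1]}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError(f"{label} must be finite and non-negative")
    return df


def two_group_de(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    pseudocount: float = PSEUDOCOUNT,
) -> DEResultTable:
    """Per-gene two-group comparison of replicate count matrices.

    ``counts_a`` / ``counts_b`` are genes x replicates with identical gene
    indexes.  Per gene: log2FC = log2((mean_b+pc)/(mean_a+pc)); p from a
    two-sided unequal-variance (Welch) t-test on log2(x+pc) replicate
    values; p_adjusted by Benjamini-Hochberg across all genes.  A gene with
    zero variance in both groups and equal means is uninformative and gets
    p = 1.
    """
    a = _as_count_frame(counts_a, "counts_a")
    b = _as_count_frame(counts_b, "counts_b")
    if not a.index.equals(b.index):
        raise ValueError("gene sets of the two groups differ")

    va = a.to_numpy(dtype=float)
    vb = b.to_numpy(dtype=float)
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    la = np.log2(va + pseudocount)
    lb = np.log2(vb + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical replicate values trigger a scipy precision warning;
        # such genes legitimately resolve to p ~ 1
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = sps.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups

    p_adj = multipletests(p, method="fdr_bh")[1]
    return DEResultTable(
        pd.DataFrame(
            {
                "gene_id": a.index.astype(str),
                "log2_fold_change": log2fc,
                "p_value": p,
                "p_adjusted": p_adj,
                "mean_expression": np.concatenate([va, vb], axis=1).mean(axis=1),
            }
        )
    )


def read_qpcr_table(path) -> list[QpcrMeasurement]:
    """Read a (sample, target_ct, housekeeping_ct, group) TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target_ct", "housekeeping_ct", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing column(s): {sorted(missing)}")
    return [
        QpcrMeasurement(
            sample_id=str(row.sample_id),
            target_ct=float(row.target_ct),
            housekeeping_ct=float(row.housekeeping_ct),
            group=str(row.group),
        )
        for row in df.itertuples()
    ]
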