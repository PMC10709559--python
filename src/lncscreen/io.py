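"""Tabular input/output for expression matrices, DE tables and time courses.

Everything is plain TSV (UTF-8, tab delimiter, ``.`` decimal point).  A
GCT-style two-line preamble (``#1.2`` followed by a dimensions line, as in
GTEx median-TPM downloads) is tolerated on read and skipped; a ``Description``
column, when present, is dropped.  Writers use a fixed decimal format so that
write-then-read round-trips are value-identical to well below 1e-9.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: printf-style format used for all floating-point serialization.
FLOAT_FORMAT = "%.15g"


class AxisKind(str, enum.Enum):
    """What the columns of an :class:`ExpressionMatrix` index."""

    tissue = "tissue"
    sample = "sample"
    timepoint = "timepoint"


@dataclass
class ExpressionMatrix:
    """A dense gene x condition matrix of TPM values.

    ``data`` is a pandas DataFrame with gene identifiers as the index and
    condition labels (tissues, samples or timepoints) as columns.  Values
    must be finite and non-negative, identifiers unique, and at least two
    conditions present — specificity and correlation are undefined on a
    single condition.
    """

    data: pd.DataFrame
    axis_kind: AxisKind = AxisKind.tissue

    def __post_init__(self) -> None:
        self.axis_kind = AxisKind(self.axis_kind)
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate condition labels: {dups}")
        if df.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs at least 2 conditions, got {df.shape[1]}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix body must be numeric")
        if np.isnan(values).any():
            bad = df.index[np.isnan(values).any(axis=1)].tolist()
            raise ValueError(f"missing values in expression matrix for genes: {bad[:5]}")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if (values < 0).any():
            bad = df.index[(values < 0).any(axis=1)].tolist()
            raise ValueError(f"negative expression values for genes: {bad[:5]}")
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    def profile(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across all conditions."""
        if gene_id not in self.data.index:
            raise KeyError(f"unknown gene: {gene_id!r}")
        return self.data.loc[gene_id].to_numpy()


#: canonical column order of a serialized DE table
DE_COLUMNS = ["gene_id", "log2_fold_change", "p_value", "p_adjusted", "mean_expression"]

# accepted header aliases (lower-cased) for DE table columns
_DE_ALIASES = {
    "gene_id": {"gene", "gene_id", "id", "geneid", "gene_name"},
    "log2_fold_change": {"log2foldchange", "log2fc", "logfc", "log2_fold_change", "lfc"},
    "p_value": {"pvalue", "p_value", "p", "pval"},
    "p_adjusted": {"padj", "p_adjusted", "fdr", "qvalue", "adj_p", "p_adj"},
    "mean_expression": {"basemean", "mean_expression", "mean", "base_mean"},
}


@dataclass
class DEResultTable:
    """Per-gene differential-expression records.

    Columns: ``gene_id``, ``log2_fold_change``, ``p_value`` and the optional
    ``p_adjusted`` / ``mean_expression`` (NaN where absent).  Row order is
    whatever the producer emitted; readers never reorder.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("gene_id", "log2_fold_change", "p_value"):
            if col not in df.columns:
                raise ValueError(f"DE table missing mandatory column {col!r}")
        for col in ("p_adjusted", "mean_expression"):
            if col not in df.columns:
                df[col] = np.nan
        df = df[DE_COLUMNS].reset_index(drop=True)
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene identifiers in DE table: {dups}")
        for col in ("p_value", "p_adjusted"):
            p = df[col].to_numpy(dtype=float)
            ok = np.isnan(p) | ((p >= 0.0) & (p <= 1.0))
            if not ok.all():
                raise ValueError(f"{col} outside [0, 1]")
        if df["p_value"].isna().any():
            logger.warning(
                "%d DE records carry a missing p-value; they will classify as "
                "not_significant",
                int(df["p_value"].isna().sum()),
            )
        me = df["mean_expression"].to_numpy(dtype=float)
        if np.any(me[~np.isnan(me)] < 0):
            raise ValueError("mean_expression must be non-negative")
        self.data = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene_id"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DifferentiationSeries:
    """An expression matrix over an ordered differentiation time course."""

    matrix: ExpressionMatrix
    timepoint_days: Sequence[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = np.asarray(self.timepoint_days, dtype=float)
        if self.matrix.axis_kind is not AxisKind.timepoint:
            raise ValueError("series matrix must have axis_kind 'timepoint'")
        if len(days) != self.matrix.n_conditions:
            raise ValueError(
                f"{len(days)} timepoints for {self.matrix.n_conditions} conditions"
            )
        if len(days) < 2:
            raise ValueError("a differentiation series needs at least 2 timepoints")
        if np.any(days < 0):
            raise ValueError("timepoint days must be non-negative")
        if np.any(np.diff(days) <= 0):
            raise ValueError("timepoint days must be strictly increasing")
        self.timepoint_days = days.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.matrix.gene_ids


def _open_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    skiprows = 2 if first.startswith("#1.2") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skiprows, comment=None, dtype={0: str})
    return df


def read_expression_matrix(
    path: str | Path,
    axis_kind: AxisKind | str = AxisKind.tissue,
    drop_incomplete: bool = False,
) -> ExpressionMatrix:
    """Read a genes x conditions TSV into a validated :class:`ExpressionMatrix`.

    First column holds gene identifiers, the header row condition labels.
    A GCT preamble is skipped when detected.  Rows or columns are never
    reordered.  Missing body values raise unless ``drop_incomplete`` is set,
    in which case incomplete genes are dropped (and logged).
    """
    df = _open_table(path)
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    if len(df.columns) and str(df.columns[0]).lower() == "description":
        df = df.drop(columns=df.columns[0])
    try:
        body = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if drop_incomplete:
        incomplete = body.index[body.isna().any(axis=1)]
        if len(incomplete):
            logger.info("dropping %d genes with missing values", len(incomplete))
            body = body.drop(index=incomplete)
    body.index = body.index.astype(str)
    return ExpressionMatrix(body, AxisKind(axis_kind))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Serialize an expression matrix as TSV with fixed decimal formatting."""
    matrix.data.to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id"
    )


def read_de_table(path: str | Path) -> DEResultTable:
    """Read a DESeq2-style results TSV, mapping common column aliases.

    Mandatory columns: gene identifier, log2 fold change, p-value.  Optional:
    adjusted p-value and mean expression; absence is recorded as NaN, never
    coerced to zero.
    """
    raw = _open_table(path)
    mapping: dict[str, str] = {}
    for col in raw.columns:
        key = str(col).strip().lower().replace(" ", "_")
        for canon, aliases in _DE_ALIASES.items():
            if key in aliases and canon not in mapping.values():
                mapping[col] = canon
                break
    df = raw.rename(columns=mapping)
    missing = [c for c in ("gene_id", "log2_fold_change", "p_value") if c not in df.columns]
    if missing:
        raise ValueError(
            f"DE table {path} lacks mandatory column(s) {missing}; "
            f"found columns {list(raw.columns)}"
        )
    keep = [c for c in DE_COLUMNS if c in df.columns]
    df = df[keep].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    for col in keep[1:]:
        df[col] = pd.to_numeric(df[col])
    return DEResultTable(df)


def write_table(records: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write any result collection as a deterministic TSV.

    Accepts a DataFrame or an iterable of records.  An empty collection
    yields a header-only file when column names are known.  Reals are
    serialized at fixed precision so a re-read reproduces values to 1e-9.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV produced by :func:`write_table`."""
    return _open_table(path)


def read_differentiation_series(
    path: str | Path, timepoint_days: Sequence[float] | None = None
) -> DifferentiationSeries:
    """Read a gene x timepoint TSV.

    When ``timepoint_days`` is omitted the column labels themselves must
    parse as numbers (e.g. ``day0  day2  day4  day7`` or ``0 2 4 7``).
    """
    matrix = read_expression_matrix(path, AxisKind.timepoint)
    if timepoint_days is None:
        days = []
        for label in matrix.condition_ids:
            digits = "".join(ch for ch in str(label) if ch.isdigit() or ch == ".")
            if not digits:
                raise ValueError(
                    f"cannot parse a day from column label {label!r}; "
                    "pass timepoint_days explicitly"
                )
            days.append(float(digits))
        timepoint_days = days
    return DifferentiationSeries(matrix, timepoint_days)
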