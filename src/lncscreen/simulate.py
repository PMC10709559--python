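"""Synthetic GTEx-like data with planted, labelled structure.

Every pipeline stage gets a no-download test bed: a gene x tissue TPM matrix
with planted one-tissue-restricted genes, a planted co-expression module
driven by a shared latent factor, replicate count matrices with planted fold
changes, and a TF panel in which designated candidates satisfy every funnel
gate while each background TF is constructed to violate one named gate.
All planted labels and effect parameters are recorded in a
:class:`SyntheticTruth` so recovery tests can compare against ground truth.

Randomness: one top-level seed fans out to per-component streams through a
fixed label-hashing rule (``_child_rng``), so adding a new generator never
perturbs the streams of existing ones.  Identical (parameters, seed) give
byte-identical outputs including serialization.

Background expression is lognormal (log2-normal mean/sd parameters): simple
and heavy-tailed like real TPM, with no attempt to match real atlas moments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AxisKind, DifferentiationSeries, ExpressionMatrix

DEFAULT_TARGET_TISSUE = "skin"
DEFAULT_COMPETING_TISSUES = ("uterus", "mammary_gland", "prostate")

#: named gates a background TF can be built to violate
TF_FAILURE_MODES = (
    "low_tissue_expression",
    "flat_trend",
    "low_query_correlation",
    "high_competing",
)


@dataclass
class SyntheticTruth:
    """Planted labels and effect parameters of one synthetic dataset."""

    seed: int
    target_tissue: str = DEFAULT_TARGET_TISSUE
    specific_gene_ids: list[str] = field(default_factory=list)
    specific_tpm: float = 0.0
    cluster_gene_ids: list[str] = field(default_factory=list)
    cluster_loading: float = 0.0
    query_gene: str | None = None
    de_down_ids: list[str] = field(default_factory=list)
    de_up_ids: list[str] = field(default_factory=list)
    effect_log2fc: float = 0.0
    candidate_tf_ids: list[str] = field(default_factory=list)
    tf_failure_modes: dict[str, str] = field(default_factory=dict)
    query_profile: np.ndarray | None = None

    def label_frame(self) -> pd.DataFrame:
        """Long-format (id, label) table of every planted assignment."""
        rows = [
            *({"id": g, "label": "specific"} for g in self.specific_gene_ids),
            *({"id": g, "label": "cluster"} for g in self.cluster_gene_ids),
            *({"id": g, "label": "de_down"} for g in self.de_down_ids),
            *({"id": g, "label": "de_up"} for g in self.de_up_ids),
            *({"id": g, "label": "candidate_tf"} for g in self.candidate_tf_ids),
            *(
                {"id": g, "label": f"background_tf:{mode}"}
                for g, mode in self.tf_failure_modes.items()
            ),
        ]
        if self.query_gene is not None:
            rows.append({"id": self.query_gene, "label": "query"})
        return pd.DataFrame(rows, columns=["id", "label"])


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-component stream keyed by a string label."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def tissue_names(
    n_tissues: int,
    target: str = DEFAULT_TARGET_TISSUE,
    competing: Sequence[str] = (),
) -> list[str]:
    """Target tissue first, then competing tissues, then generic fillers."""
    named = [target, *competing]
    if n_tissues < len(named):
        raise ValueError(f"n_tissues={n_tissues} < {len(named)} named tissues")
    fillers = [f"tissue_{i:02d}" for i in range(len(named) + 1, n_tissues + 1)]
    return named + fillers


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_tissue_matrix(
    n_genes: int = 2000,
    n_tissues: int = 58,
    n_specific: int = 50,
    specific_tpm: float = 100.0,
    background_log2_mean: float = 0.0,
    background_log2_sd: float = 0.5,
    target_tissue: str = DEFAULT_TARGET_TISSUE,
    tissue_labels: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Background lognormal TPM with ``n_specific`` target-restricted genes.

    Background values are i.i.d. ``2**Normal(mean, sd)`` per gene per tissue
    (defaults centre on ~1 TPM).  Planted genes additionally receive
    ``specific_tpm`` in the target tissue only, giving a near-one-hot profile
    whose specificity score approaches ``sqrt(n_tissues)``.  ``tissue_labels``
    overrides the generated condition names (the target must come first).
    """
    if n_specific > n_genes:
        raise ValueError("n_specific cannot exceed n_genes")
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = _child_rng(seed, "tissue_matrix")
    genes = _gene_ids(n_genes)
    if tissue_labels is not None:
        tissues = list(tissue_labels)
        if len(tissues) != n_tissues or tissues[0] != target_tissue:
            raise ValueError("tissue_labels must have n_tissues entries, target first")
    else:
        tissues = tissue_names(n_tissues, target=target_tissue)

    values = 2.0 ** rng.normal(background_log2_mean, background_log2_sd, (n_genes, n_tissues))
    planted_idx = np.sort(rng.choice(n_genes, size=n_specific, replace=False))
    values[planted_idx, 0] += specific_tpm  # target tissue is column 0

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=tissues), AxisKind.tissue
    )
    truth = SyntheticTruth(
        seed=seed,
        target_tissue=target_tissue,
        specific_gene_ids=[genes[i] for i in planted_idx],
        specific_tpm=specific_tpm,
    )
    return matrix, truth


def simulate_coexpression_cluster(
    matrix: ExpressionMatrix,
    query_gene: str,
    cluster_size: int = 30,
    loading: float = 0.8,
    noise_sd: float = 0.1,
    cluster_log2_mean: float = 3.0,
    cluster_log2_sd: float = 1.0,
    exclude: Sequence[str] = (),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Plant a co-expression module sharing the query's latent factor.

    The factor is the query's standardized log2(TPM+1) profile.  Each
    cluster gene's log-profile is rebuilt as the standardized mixture
    ``loading*factor + (1-loading)*background + noise`` rescaled to
    (``cluster_log2_mean``, ``cluster_log2_sd``); TPM is recovered as
    ``2**log2 - 1`` so that log2(TPM+1) is exactly affine in the mixture.
    With independent standardized components the population correlation
    between a cluster gene and the factor is
    ``loading / sqrt(loading**2 + (1-loading)**2 + noise_sd**2)``
    (~0.96 at the defaults).

    Cluster members are drawn from genes other than the query and
    ``exclude``; the returned matrix replaces their profiles in place.
    """
    if not (0.0 < loading <= 1.0):
        raise ValueError("loading must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if query_gene not in matrix.data.index:
        raise KeyError(f"query gene {query_gene!r} not in matrix")
    eligible = [
        g for g in matrix.gene_ids if g != query_gene and g not in set(exclude)
    ]
    if cluster_size > len(eligible):
        raise ValueError("cluster_size exceeds the number of eligible genes")

    rng = _child_rng(seed, "coexpression_cluster")
    cluster = sorted(rng.choice(eligible, size=cluster_size, replace=False).tolist())

    def _standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd

    factor = _standardize(np.log2(matrix.profile(query_gene) + 1.0))
    data = matrix.data.copy()
    for g in cluster:
        background = _standardize(np.log2(matrix.profile(g) + 1.0))
        eps = rng.normal(0.0, 1.0, matrix.n_conditions)
        mix = loading * factor + (1.0 - loading) * background + noise_sd * eps
        z = _standardize(mix)
        log2_profile = cluster_log2_mean + cluster_log2_sd * z
        data.loc[g] = np.maximum(2.0 ** log2_profile - 1.0, 0.0)

    truth = SyntheticTruth(
        seed=seed,
        cluster_gene_ids=cluster,
        cluster_loading=loading,
        query_gene=query_gene,
    )
    return ExpressionMatrix(data, matrix.axis_kind), truth


def simulate_de_counts(
    n_genes: int = 2000,
    n_de: int = 40,
    effect_log2fc: float = 4.0,
    n_reps: int = 3,
    dispersion: float = 0.1,
    baseline_log2_mean: float = 7.0,
    baseline_log2_sd: float = 1.5,
    gene_ids: Sequence[str] | None = None,
    down_gene_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Replicate count matrices for a two-condition contrast.

    Counts are a lognormal-Poisson mixture: per-gene baseline mean
    ``2**Normal(baseline_log2_mean, baseline_log2_sd)``, per-replicate
    log2-scale noise of sd ``dispersion``, Poisson sampling on top.  Planted
    genes change by ``2**(+-effect_log2fc)`` in condition B, split evenly
    between up and down (an odd ``n_de`` gives the extra gene to the down
    set).  Passing ``down_gene_ids`` pins which genes form the down set —
    used by the pipeline to make the tissue-restricted genes the
    knock-down-repressed ones.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per group")
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    if len(genes) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    rng = _child_rng(seed, "de_counts")
    pos = {g: i for i, g in enumerate(genes)}

    if down_gene_ids is not None:
        down_idx = np.array([pos[g] for g in down_gene_ids], dtype=int)
        if len(down_idx) > n_de:
            raise ValueError("more down_gene_ids than n_de")
        remaining = np.setdiff1d(np.arange(n_genes), down_idx)
        up_idx = np.sort(rng.choice(remaining, size=n_de - len(down_idx), replace=False))
    else:
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        n_down = (n_de + 1) // 2
        down_idx = np.sort(de_idx[:n_down])
        up_idx = np.sort(de_idx[n_down:])

    baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, n_genes)
    effect = np.zeros(n_genes)
    effect[down_idx] = -effect_log2fc
    effect[up_idx] = effect_log2fc

    def _draw(mean_per_gene: np.ndarray) -> np.ndarray:
        noisy = mean_per_gene[:, None] * 2.0 ** rng.normal(0.0, dispersion, (n_genes, n_reps))
        return rng.poisson(noisy).astype(float)

    counts_a = pd.DataFrame(
        _draw(baseline), index=genes, columns=[f"A{r+1}" for r in range(n_reps)]
    )
    counts_b = pd.DataFrame(
        _draw(baseline * 2.0 ** effect),
        index=genes,
        columns=[f"B{r+1}" for r in range(n_reps)],
    )
    truth = SyntheticTruth(
        seed=seed,
        de_down_ids=[genes[i] for i in down_idx],
        de_up_ids=[genes[i] for i in up_idx],
        effect_log2fc=effect_log2fc,
    )
    return counts_a, counts_b, truth


def simulate_tf_panel(
    n_tfs: int = 60,
    n_candidates: int = 6,
    series_timepoints: Sequence[float] = (0.0, 2.0, 4.0, 7.0),
    target_tissue: str = DEFAULT_TARGET_TISSUE,
    competing_tissues: Sequence[str] = DEFAULT_COMPETING_TISSUES,
    n_tissues: int = 58,
    candidate_tissue_tpm: float = 30.0,
    query_tpm: float = 50.0,
    seed: int = 0,
) -> tuple[list[str], ExpressionMatrix, DifferentiationSeries, SyntheticTruth]:
    """A TF catalogue with planted funnel survivors and labelled decoys.

    Candidates are target-tissue-high (+``candidate_tissue_tpm`` TPM over a
    ~1 TPM background), rise over the time course (first-to-last log2 ratio
    ~3), correlate with the planted query profile across tissues (both are
    target-tissue spikes) and stay at background level in competing tissues.
    Each background TF is assigned one failure mode, cycling through
    ``TF_FAILURE_MODES``, and is built to violate exactly that gate while
    satisfying the gates evaluated before it:

    - ``low_tissue_expression``: whole profile scaled to ~0.05 TPM;
    - ``flat_trend``: target-high but flat over the course;
    - ``low_query_correlation``: broadly expressed (~20 TPM everywhere),
      rising, but uncorrelated with the query's spike;
    - ``high_competing``: spiked in the target AND the first competing
      tissue, so the competing Z-difference collapses to ~0.

    Returns ``(catalogue, tissue matrix, series, truth)``; the query's
    tissue profile is stored in ``truth.query_profile``.
    """
    if n_candidates > n_tfs:
        raise ValueError("n_candidates cannot exceed n_tfs")
    if not competing_tissues:
        raise ValueError("need at least one competing tissue")
    rng = _child_rng(seed, "tf_panel")
    tfs = _gene_ids(n_tfs, prefix="TF")
    tissues = tissue_names(n_tissues, target=target_tissue, competing=competing_tissues)
    days = np.asarray(series_timepoints, dtype=float)

    candidate_idx = np.sort(rng.choice(n_tfs, size=n_candidates, replace=False))
    candidate_set = set(candidate_idx.tolist())
    background_idx = [i for i in range(n_tfs) if i not in candidate_set]
    modes = {
        tfs[i]: TF_FAILURE_MODES[j % len(TF_FAILURE_MODES)]
        for j, i in enumerate(background_idx)
    }

    # tissue profiles: lognormal ~1 TPM background plus mode-specific structure
    expr = 2.0 ** rng.normal(0.0, 0.5, (n_tfs, n_tissues))
    competing_col = 1  # first competing tissue follows the target (column 0)
    for i in range(n_tfs):
        mode = None if i in candidate_set else modes[tfs[i]]
        if mode is None:
            expr[i, 0] += candidate_tissue_tpm
        elif mode == "low_tissue_expression":
            expr[i] *= 0.05
        elif mode == "flat_trend":
            expr[i, 0] += candidate_tissue_tpm
        elif mode == "low_query_correlation":
            expr[i] = 20.0 * 2.0 ** rng.normal(0.0, 0.5, n_tissues)
        elif mode == "high_competing":
            expr[i, 0] += candidate_tissue_tpm
            expr[i, competing_col] += candidate_tissue_tpm

    tissue_matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=tfs, columns=tissues), AxisKind.tissue
    )

    # differentiation course: geometric rise 2 -> 23 TPM (trend ~3) or flat 8
    frac = (days - days[0]) / (days[-1] - days[0])
    rising_shape = 2.0 * (23.0 / 2.0) ** frac
    flat_shape = np.full(len(days), 8.0)
    series_vals = np.empty((n_tfs, len(days)))
    for i in range(n_tfs):
        mode = None if i in candidate_set else modes[tfs[i]]
        shape = flat_shape if mode == "flat_trend" else rising_shape
        series_vals[i] = shape * 2.0 ** rng.normal(0.0, 0.05, len(days))
    series = DifferentiationSeries(
        ExpressionMatrix(
            pd.DataFrame(
                series_vals, index=tfs, columns=[f"day{d:g}" for d in days]
            ),
            AxisKind.timepoint,
        ),
        days,
    )

    query_profile = 2.0 ** rng.normal(-1.0, 0.5, n_tissues)
    query_profile[0] += query_tpm

    truth = SyntheticTruth(
        seed=seed,
        target_tissue=target_tissue,
        candidate_tf_ids=[tfs[i] for i in candidate_idx],
        tf_failure_modes=modes,
        query_profile=query_profile,
    )
    return tfs, tissue_matrix, series, truth
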