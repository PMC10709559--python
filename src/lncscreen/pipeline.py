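"""End-to-end orchestration: simulate or ingest, then run every stage.

``run_all`` executes, in order: data acquisition (synthetic generation or
TSV ingestion), the two-group DE fit (simulation mode only — ingested DE
tables are used as-is), DE classification and counts, tissue-specificity
scoring, the abundance+specificity+DE candidate gate, co-expression ranking
around the query gene, and the TF screening funnel.  Every stage writes its
table to the output directory and the run manifest records paths, the exact
parameters, per-stage counts, versions and the seed — the manifest alone is
enough to re-run the pipeline identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coexpression import top_coexpressed
from .de import classify_de, summarize_counts
from .io import (
    AxisKind,
    read_de_table,
    read_differentiation_series,
    read_expression_matrix,
    write_expression_matrix,
    write_table,
)
from .simulate import (
    DEFAULT_COMPETING_TISSUES,
    simulate_coexpression_cluster,
    simulate_de_counts,
    simulate_tf_panel,
    simulate_tissue_matrix,
    tissue_names,
)
from .specificity import select_candidates, specificity_score
from .stats import two_group_de
from .tf_screen import TFScreenConfig, funnel_counts, screen_tfs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults mirror the printed gates.

    Either ``simulate=True`` (with the simulation block) or all four input
    paths plus ``query_gene`` must be provided.
    """

    out_dir: str = "lncscreen_run"
    seed: int = 0
    target_tissue: str = "skin"
    log_level: str = "INFO"

    # --- input mode -------------------------------------------------------
    simulate: bool = True
    matrix_path: str | None = None
    de_table_path: str | None = None
    series_path: str | None = None
    catalogue_path: str | None = None
    tf_matrix_path: str | None = None  # defaults to matrix_path
    query_gene: str | None = None

    # --- simulation block -------------------------------------------------
    n_genes: int = 2000
    n_tissues: int = 58
    n_specific: int = 50
    specific_tpm: float = 100.0
    background_log2_mean: float = 0.0
    background_log2_sd: float = 0.5
    cluster_size: int = 30
    cluster_loading: float = 0.8
    cluster_noise_sd: float = 0.1
    n_de_up: int = 50
    effect_log2fc: float = 4.0
    n_reps: int = 3
    dispersion: float = 0.1
    n_tfs: int = 60
    n_candidate_tfs: int = 6
    series_timepoints: list[float] = field(default_factory=lambda: [0.0, 2.0, 4.0, 7.0])

    # --- stage thresholds (defaults = the published gates) ----------------
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    use_adjusted: bool = False
    direction: str = "down"
    min_tpm: float = 10.0
    min_score: float = 5.0
    top_k: int = 500
    min_tissue_tpm: float = 1.0
    trend_min_log2fc: float = 1.0
    min_query_r: float = 0.5
    min_competing_delta: float = 1.0
    competing_tissues: list[str] = field(
        default_factory=lambda: list(DEFAULT_COMPETING_TISSUES)
    )

    def validate(self) -> None:
        for name in ("lfc_threshold", "p_threshold", "min_tpm", "min_score", "top_k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.simulate:
            missing = [
                name
                for name in (
                    "matrix_path",
                    "de_table_path",
                    "series_path",
                    "catalogue_path",
                    "query_gene",
                )
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(
                    f"input mode requires {missing}; or set simulate=True"
                )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "lncscreen",
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": {},
        "counts": {},
    }

    def _write(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        manifest["outputs"][name.split(".")[0]] = name

    stage = "acquire"
    t0 = time.perf_counter()
    try:
        if config.simulate:
            labels = tissue_names(
                config.n_tissues, config.target_tissue, config.competing_tissues
            )
            matrix, spec_truth = simulate_tissue_matrix(
                n_genes=config.n_genes,
                n_tissues=config.n_tissues,
                n_specific=config.n_specific,
                specific_tpm=config.specific_tpm,
                background_log2_mean=config.background_log2_mean,
                background_log2_sd=config.background_log2_sd,
                target_tissue=config.target_tissue,
                tissue_labels=labels,
                seed=config.seed,
            )
            query_gene = spec_truth.specific_gene_ids[0]
            matrix, cluster_truth = simulate_coexpression_cluster(
                matrix,
                query_gene,
                cluster_size=config.cluster_size,
                loading=config.cluster_loading,
                noise_sd=config.cluster_noise_sd,
                exclude=spec_truth.specific_gene_ids,
                seed=config.seed,
            )
            counts_a, counts_b, de_truth = simulate_de_counts(
                n_genes=config.n_genes,
                n_de=config.n_specific + config.n_de_up,
                effect_log2fc=config.effect_log2fc,
                n_reps=config.n_reps,
                dispersion=config.dispersion,
                gene_ids=matrix.gene_ids,
                down_gene_ids=spec_truth.specific_gene_ids,
                seed=config.seed,
            )
            catalogue, tf_matrix, series, tf_truth = simulate_tf_panel(
                n_tfs=config.n_tfs,
                n_candidates=config.n_candidate_tfs,
                series_timepoints=config.series_timepoints,
                target_tissue=config.target_tissue,
                competing_tissues=config.competing_tissues,
                n_tissues=config.n_tissues,
                seed=config.seed,
            )
            de_table = two_group_de(counts_a, counts_b)
            query_profile = matrix.profile(query_gene)

            _write("tissue_matrix.tsv", write_expression_matrix, matrix)
            _write("tf_matrix.tsv", write_expression_matrix, tf_matrix)
            _write("series.tsv", write_expression_matrix, series.matrix)
            _write("counts_a.tsv", write_table, counts_a.reset_index(names="gene_id"))
            _write("counts_b.tsv", write_table, counts_b.reset_index(names="gene_id"))
            (out / "catalogue.txt").write_text("\n".join(catalogue) + "\n")
            manifest["outputs"]["catalogue"] = "catalogue.txt"
            truth = pd.concat(
                [
                    spec_truth.label_frame(),
                    cluster_truth.label_frame(),
                    de_truth.label_frame(),
                    tf_truth.label_frame(),
                ],
                ignore_index=True,
            )
            _write("truth.tsv", write_table, truth)
            manifest["counts"]["n_genes"] = matrix.n_genes
        else:
            matrix = read_expression_matrix(config.matrix_path, AxisKind.tissue)
            de_table = read_de_table(config.de_table_path)
            series = read_differentiation_series(config.series_path)
            catalogue = [
                line.strip()
                for line in Path(config.catalogue_path).read_text().splitlines()
                if line.strip()
            ]
            tf_matrix = (
                read_expression_matrix(config.tf_matrix_path, AxisKind.tissue)
                if config.tf_matrix_path
                else matrix
            )
            query_gene = config.query_gene
            query_profile = matrix.profile(query_gene)
            manifest["counts"]["n_genes"] = matrix.n_genes
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    def _run_stage(name: str, fn):
        t = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001
            raise StageError(name, exc) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t)
        return result

    def _de_stage():
        _write("de_table.tsv", write_table, de_table.data)
        classes = classify_de(
            de_table,
            lfc_threshold=config.lfc_threshold,
            p_threshold=config.p_threshold,
            use_adjusted=config.use_adjusted,
        )
        _write("de_classification.tsv", write_table, classes)
        n_down, n_up = summarize_counts(classes)
        manifest["counts"]["de_down"] = n_down
        manifest["counts"]["de_up"] = n_up
        return classes

    _run_stage("de_screen", _de_stage)

    def _specificity_stage():
        spec = specificity_score(matrix, config.target_tissue)
        _write("specificity.tsv", write_table, spec)
        return spec

    spec = _run_stage("specificity", _specificity_stage)

    def _candidate_stage():
        cands = select_candidates(
            spec,
            de_table,
            min_tpm=config.min_tpm,
            min_score=config.min_score,
            direction=config.direction,
            lfc_threshold=config.lfc_threshold,
            p_threshold=config.p_threshold,
            use_adjusted=config.use_adjusted,
        )
        _write("candidates.tsv", write_table, cands)
        manifest["counts"]["candidates"] = len(cands)
        manifest["candidate_gene_ids"] = list(cands["gene_id"])
        return cands

    _run_stage("candidate_gate", _candidate_stage)

    def _coexpression_stage():
        top = top_coexpressed(matrix, query_gene, k=config.top_k)
        _write("coexpression_top.tsv", write_table, top)
        manifest["counts"]["top_k_size"] = len(top)
        manifest["query_gene"] = query_gene
        return top

    _run_stage("coexpression", _coexpression_stage)

    def _tf_stage():
        tf_config = TFScreenConfig(
            min_tissue_tpm=config.min_tissue_tpm,
            trend_min_log2fc=config.trend_min_log2fc,
            min_query_r=config.min_query_r,
            competing_tissues=list(config.competing_tissues),
            min_competing_delta=config.min_competing_delta,
        )
        outcome = screen_tfs(
            catalogue,
            tf_matrix,
            series,
            np.asarray(query_profile),
            config.target_tissue,
            tf_config,
        )
        _write("tf_screen.tsv", write_table, outcome.results)
        _write("tf_candidates.tsv", write_table, outcome.candidates)
        total, stage1, final = funnel_counts(outcome)
        manifest["counts"]["tf_catalogue"] = total
        manifest["counts"]["tf_stage1"] = stage1
        manifest["counts"]["tf_final"] = final
        manifest["tf_candidate_ids"] = sorted(outcome.candidates["tf_id"])
        return outcome

    _run_stage("tf_screen", _tf_stage)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
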