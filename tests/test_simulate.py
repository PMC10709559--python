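import numpy as np
import pandas as pd
import pytest

from lncscreen import (
    classify_de,
    screen_tfs,
    simulate_coexpression_cluster,
    simulate_de_counts,
    simulate_tf_panel,
    simulate_tissue_matrix,
    specificity_score,
    top_coexpressed,
    two_group_de,
    TFScreenConfig,
)
from lncscreen.simulate import DEFAULT_COMPETING_TISSUES, tissue_names


class TestTissueMatrix:
    def test_same_seed_reproduces_identical_matrix(self):
        m1, t1 = simulate_tissue_matrix(n_genes=100, n_specific=5, seed=42)
        m2, t2 = simulate_tissue_matrix(n_genes=100, n_specific=5, seed=42)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert t1.specific_gene_ids == t2.specific_gene_ids

    def test_different_seed_changes_values(self):
        m1, _ = simulate_tissue_matrix(n_genes=50, n_specific=0, seed=1)
        m2, _ = simulate_tissue_matrix(n_genes=50, n_specific=0, seed=2)
        assert not np.array_equal(m1.values, m2.values)

    def test_no_planted_genes_means_empty_truth(self):
        _, truth = simulate_tissue_matrix(n_genes=50, n_specific=0, seed=0)
        assert truth.specific_gene_ids == []

    def test_planted_ids_are_subset_of_universe(self):
        m, truth = simulate_tissue_matrix(n_genes=100, n_specific=10, seed=0)
        assert set(truth.specific_gene_ids) <= set(m.gene_ids)

    def test_planted_gene_is_target_enriched(self):
        m, truth = simulate_tissue_matrix(n_genes=200, n_specific=5, specific_tpm=100, seed=0)
        scores = specificity_score(m, "skin").set_index("gene_id")
        assert (scores.loc[truth.specific_gene_ids, "score"] > 5).all()

    def test_zero_effect_removes_recovery(self):
        """Honest dial: no planted TPM, no recoverable specificity signal."""
        m, truth = simulate_tissue_matrix(n_genes=200, n_specific=5, specific_tpm=0.0, seed=0)
        scores = specificity_score(m, "skin").set_index("gene_id")
        assert not (scores.loc[truth.specific_gene_ids, "score"] > 5).any()

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_tissue_matrix(n_genes=5, n_specific=10, seed=0)


class TestCoexpressionCluster:
    def test_degenerate_limit_perfect_correlation(self):
        m, _ = simulate_tissue_matrix(n_genes=50, n_specific=0, seed=0)
        query = m.gene_ids[0]
        planted, truth = simulate_coexpression_cluster(
            m, query, cluster_size=5, loading=1.0, noise_sd=0.0, seed=0
        )
        top = top_coexpressed(planted, query, k=5)
        assert set(top["gene_id"]) == set(truth.cluster_gene_ids)
        np.testing.assert_allclose(top["pearson_r"], 1.0, atol=1e-9)

    def test_zero_loading_rejected(self):
        m, _ = simulate_tissue_matrix(n_genes=50, n_specific=0, seed=0)
        with pytest.raises(ValueError, match="loading"):
            simulate_coexpression_cluster(m, m.gene_ids[0], loading=0.0, seed=0)

    def test_query_never_in_its_own_cluster(self):
        m, _ = simulate_tissue_matrix(n_genes=50, n_specific=0, seed=0)
        query = m.gene_ids[0]
        _, truth = simulate_coexpression_cluster(m, query, cluster_size=10, seed=0)
        assert query not in truth.cluster_gene_ids

    def test_low_loading_breaks_recovery(self):
        """Honest dial: near-zero loading must not fill the top ranks."""
        m, _ = simulate_tissue_matrix(n_genes=500, n_specific=0, seed=0)
        query = m.gene_ids[0]
        planted, truth = simulate_coexpression_cluster(
            m, query, cluster_size=20, loading=0.05, noise_sd=1.0, seed=0
        )
        top = top_coexpressed(planted, query, k=20)
        assert set(top["gene_id"]) != set(truth.cluster_gene_ids)


class TestDECounts:
    def test_determinism(self):
        a1, b1, t1 = simulate_de_counts(n_genes=100, n_de=10, seed=9)
        a2, b2, t2 = simulate_de_counts(n_genes=100, n_de=10, seed=9)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
        assert t1.de_down_ids == t2.de_down_ids

    def test_even_split_between_directions(self):
        _, _, truth = simulate_de_counts(n_genes=100, n_de=10, seed=0)
        assert len(truth.de_down_ids) == len(truth.de_up_ids) == 5

    def test_odd_n_de_gives_extra_to_down(self):
        _, _, truth = simulate_de_counts(n_genes=100, n_de=7, seed=0)
        assert len(truth.de_down_ids) == 4
        assert len(truth.de_up_ids) == 3

    def test_strong_effect_fully_recovered_with_direction(self):
        a, b, truth = simulate_de_counts(n_genes=500, n_de=20, effect_log2fc=4.0, seed=0)
        classes = classify_de(two_group_de(a, b)).set_index("gene_id")
        assert (classes.loc[truth.de_down_ids, "status"] == "down").all()
        assert (classes.loc[truth.de_up_ids, "status"] == "up").all()

    def test_zero_effect_is_null(self):
        """Honest dial: effect 0 leaves planted genes indistinguishable."""
        a, b, truth = simulate_de_counts(n_genes=500, n_de=20, effect_log2fc=0.0, seed=0)
        classes = classify_de(two_group_de(a, b))
        n_called = (classes["status"] != "not_significant").sum()
        assert n_called < 0.02 * 500  # needs |lfc|>1 too, so ~none under the null

    def test_pinned_down_gene_ids(self):
        genes = [f"g{i}" for i in range(100)]
        _, _, truth = simulate_de_counts(
            n_genes=100, n_de=10, gene_ids=genes, down_gene_ids=genes[:6], seed=0
        )
        assert truth.de_down_ids == genes[:6]
        assert len(truth.de_up_ids) == 4


class TestTFPanel:
    def test_determinism_and_truth_subsets(self):
        c1, m1, s1, t1 = simulate_tf_panel(seed=4)
        c2, m2, s2, t2 = simulate_tf_panel(seed=4)
        assert c1 == c2
        np.testing.assert_array_equal(m1.values, m2.values)
        np.testing.assert_array_equal(s1.matrix.values, s2.matrix.values)
        assert t1.candidate_tf_ids == t2.candidate_tf_ids
        assert set(t1.candidate_tf_ids) <= set(c1)
        assert set(t1.tf_failure_modes) == set(c1) - set(t1.candidate_tf_ids)

    def test_tissue_axis_has_target_then_competing(self):
        _, m, _, _ = simulate_tf_panel(seed=0)
        assert m.condition_ids[:4] == ["skin", *DEFAULT_COMPETING_TISSUES]

    def test_tissue_names_helper_validates(self):
        with pytest.raises(ValueError):
            tissue_names(2, "skin", ["uterus", "prostate"])

    def test_zero_candidates_recovery_honest(self):
        catalogue, matrix, series, truth = simulate_tf_panel(n_candidates=0, seed=0)
        outcome = screen_tfs(
            catalogue,
            matrix,
            series,
            truth.query_profile,
            "skin",
            TFScreenConfig(competing_tissues=list(DEFAULT_COMPETING_TISSUES)),
        )
        assert outcome.candidates.empty

    def test_label_frame_collects_all_assignments(self):
        _, _, _, truth = simulate_tf_panel(n_tfs=20, n_candidates=3, seed=0)
        frame = truth.label_frame()
        assert (frame["label"] == "candidate_tf").sum() == 3
        assert frame["label"].str.startswith("background_tf:").sum() == 17
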