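import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncscreen import (
    AxisKind,
    DEResultTable,
    ExpressionMatrix,
    select_candidates,
    specificity_score,
    zscore_profile,
)


def oracle_specificity(values: np.ndarray, target_idx: int) -> float:
    """First-principles per-gene loop: mean, sample sd, Z, Z-difference."""
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    if sd == 0:
        return 0.0
    z = [(v - mean) / sd for v in values]
    others = [z[i] for i in range(n) if i != target_idx]
    return z[target_idx] - max(others)


class TestZScoreProfile:
    def test_constant_vector_is_degenerate_all_zero(self):
        z, degenerate = zscore_profile([5.0, 5.0, 5.0, 5.0])
        assert degenerate
        np.testing.assert_array_equal(z, np.zeros(4))

    def test_hand_computed_example(self):
        # mean 4, sample sd 4 -> (1.5, -0.5, -0.5, -0.5)
        z, degenerate = zscore_profile([10.0, 2.0, 2.0, 2.0])
        assert not degenerate
        np.testing.assert_allclose(z, [1.5, -0.5, -0.5, -0.5])

    @pytest.mark.parametrize("n", [2, 4, 10, 58])
    def test_one_hot_closed_form(self, n):
        # single non-zero entry: Z at that entry is (n-1)/sqrt(n) under sample sd
        x = np.zeros(n)
        x[0] = 7.0
        z, _ = zscore_profile(x)
        assert z[0] == pytest.approx((n - 1) / math.sqrt(n), abs=1e-12)

    def test_too_short_vector_raises(self):
        with pytest.raises(ValueError):
            zscore_profile([1.0])


class TestSpecificityScore:
    def test_worked_example(self, small_matrix):
        result = specificity_score(small_matrix, "skin")
        row = result.set_index("gene_id").loc["g_spec"]
        assert row["z_target"] == pytest.approx(1.5)
        assert row["z_max_other"] == pytest.approx(-0.5)
        assert row["score"] == pytest.approx(2.0)

    def test_one_hot_gene_scores_sqrt_n(self):
        n = 58
        values = np.zeros((1, n))
        values[0, 0] = 100.0
        m = ExpressionMatrix(
            pd.DataFrame(values, index=["g"], columns=[f"t{i}" for i in range(n)])
        )
        score = specificity_score(m, "t0")["score"].iloc[0]
        assert score == pytest.approx(math.sqrt(n), abs=1e-9)

    def test_constant_gene_degenerate_zero(self, small_matrix):
        row = specificity_score(small_matrix, "skin").set_index("gene_id").loc["g_flat"]
        assert row["score"] == 0.0
        assert bool(row["degenerate"])

    def test_unknown_target_tissue_raises(self, small_matrix):
        with pytest.raises(KeyError):
            specificity_score(small_matrix, "kidney")

    def test_results_follow_input_gene_order(self, small_matrix):
        assert list(specificity_score(small_matrix, "skin")["gene_id"]) == small_matrix.gene_ids

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(10):
            values = 2.0 ** rng.normal(0, 2, size=(200, 20))
            m = ExpressionMatrix(
                pd.DataFrame(
                    values,
                    index=[f"g{i}" for i in range(200)],
                    columns=[f"t{j}" for j in range(20)],
                )
            )
            target = int(rng.integers(20))
            scores = specificity_score(m, f"t{target}")["score"].to_numpy()
            expected = np.array([oracle_specificity(row, target) for row in values])
            assert np.max(np.abs(scores - expected)) < 1e-10

    def test_sign_semantics(self, rng):
        """score > 0 exactly when the target Z strictly leads all others."""
        values = 2.0 ** rng.normal(0, 1, size=(300, 8))
        m = ExpressionMatrix(
            pd.DataFrame(
                values, index=[f"g{i}" for i in range(300)], columns=[f"t{j}" for j in range(8)]
            )
        )
        res = specificity_score(m, "t0")
        is_max = values[:, 0] > values[:, 1:].max(axis=1)
        np.testing.assert_array_equal((res["score"] > 0).to_numpy(), is_max)

    @settings(derandomize=True, max_examples=50)
    @given(
        others=st.lists(st.floats(0.1, 100.0), min_size=3, max_size=12),
        target=st.floats(0.1, 100.0),
        bump=st.floats(0.5, 50.0),
    )
    def test_monotone_in_target_expression(self, others, target, bump):
        """Raising the target-tissue value never lowers the score."""
        base = np.array([target] + others)
        bumped = base.copy()
        bumped[0] += bump
        if base.std() == 0 or bumped.std() == 0:
            return
        assert oracle_specificity(bumped, 0) >= oracle_specificity(base, 0) - 1e-12


class TestSelectCandidates:
    @pytest.fixture
    def five_gene_setup(self):
        spec = pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC", "gD", "gE"],
                "target_expression": [20.0, 15.0, 5.0, 20.0, 30.0],
                "score": [6.0, 8.0, 6.0, 4.0, 7.0],
                "degenerate": False,
            }
        )
        de = DEResultTable(
            pd.DataFrame(
                {
                    "gene_id": ["gA", "gB", "gC", "gD", "gE"],
                    "log2_fold_change": [-2.0, -3.0, -2.0, -2.0, 3.0],
                    "p_value": [0.01, 0.001, 0.01, 0.01, 0.001],
                }
            )
        )
        return spec, de

    def test_exhaustive_enumeration_of_gates(self, five_gene_setup):
        """Of 5 genes only gB (score 8) and gA (score 6) pass all three gates."""
        spec, de = five_gene_setup
        out = select_candidates(spec, de)
        assert list(out["gene_id"]) == ["gB", "gA"]

    def test_gates_are_strict(self):
        spec = pd.DataFrame(
            {
                "gene_id": ["on_tpm", "on_score"],
                "target_expression": [10.0, 50.0],
                "score": [9.0, 5.0],
            }
        )
        de = DEResultTable(
            pd.DataFrame(
                {
                    "gene_id": ["on_tpm", "on_score"],
                    "log2_fold_change": [-5.0, -5.0],
                    "p_value": [1e-6, 1e-6],
                }
            )
        )
        assert select_candidates(spec, de).empty  # ==10 TPM and ==5 both fail

    def test_empty_spec_gives_empty_candidates(self, five_gene_setup):
        _, de = five_gene_setup
        empty = pd.DataFrame(columns=["gene_id", "target_expression", "score"])
        assert select_candidates(empty, de).empty

    def test_direction_any_admits_up_genes(self, five_gene_setup):
        spec, de = five_gene_setup
        out = select_candidates(spec, de, direction="any")
        assert "gE" in set(out["gene_id"])

    def test_score_ties_break_by_abs_lfc_then_id(self):
        spec = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "target_expression": 20.0,
                "score": 6.0,
            }
        )
        de = DEResultTable(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2", "g3"],
                    "log2_fold_change": [-2.0, -4.0, -2.0],
                    "p_value": 0.01,
                }
            )
        )
        assert list(select_candidates(spec, de)["gene_id"]) == ["g2", "g1", "g3"]
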