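import numpy as np
import pandas as pd
import pytest

from lncscreen import AxisKind, DEResultTable, ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 tissues with one obviously skin-restricted gene."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[10.0, 2.0, 2.0, 2.0], [5.0, 5.0, 5.0, 5.0], [1.0, 8.0, 3.0, 2.0]],
            index=["g_spec", "g_flat", "g_other"],
            columns=["skin", "liver", "lung", "brain"],
        ),
        AxisKind.tissue,
    )


@pytest.fixture
def six_gene_de_table() -> DEResultTable:
    """Enumerable fixture: exactly one up and one down call under strict gates.

    (log2FC=1.0, p=.01) sits exactly on the fold-change threshold and must
    NOT be called; (-3, .06) misses the p gate.
    """
    return DEResultTable(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(1, 7)],
                "log2_fold_change": [2.0, 1.0, -3.0, -3.0, 0.5, 4.0],
                "p_value": [0.01, 0.01, 0.04, 0.06, 0.001, 0.2],
            }
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230419)
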