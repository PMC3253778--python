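import numpy as np
import pandas as pd
import pytest

from grnmeta import (
    DatasetEnsemble,
    Edge,
    EdgeScoreTable,
    ExpressionDataset,
    GeneNetwork,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain_network():
    """a -> b -> c plus an isolated gene d."""
    return GeneNetwork(["a", "b", "c", "d"], [Edge("a", "b"), Edge("b", "c")])


@pytest.fixture
def random_dataset(rng):
    genes = [f"g{i}" for i in range(5)]
    return ExpressionDataset("rand5", genes, rng.normal(size=(5, 60)))


@pytest.fixture
def null_ensemble(rng):
    """Three datasets of independent genes (no true edges)."""
    genes = [f"g{i}" for i in range(6)]
    return DatasetEnsemble(
        [
            ExpressionDataset(f"null{k}", genes, rng.normal(size=(6, 80)))
            for k in range(3)
        ]
    )


def make_score_table(pairs, scores, p_values=None, method="rn", effects=None):
    """Build a minimal EdgeScoreTable from explicit pair data."""
    n = len(pairs)
    if p_values is None:
        p_values = [np.nan] * n
    if effects is None:
        effects = scores
    return EdgeScoreTable(
        pd.DataFrame(
            {
                "gene_a": [a for a, _ in pairs],
                "gene_b": [b for _, b in pairs],
                "effect": effects,
                "score": scores,
                "statistic": scores,
                "p_value": p_values,
            }
        ),
        method=method,
    )


@pytest.fixture
def score_table_factory():
    return make_score_table
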