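import numpy as np
import pandas as pd
import pytest

from coexkit import CoexpressionTable, FixtureConfig, default_collection
from coexkit.expression import ExpressionMatrix


def random_mr_table(n_genes: int, seed: int, prefix: str = "g") -> CoexpressionTable:
    """A valid MR table from random Gaussian expression (null structure)."""
    from coexkit.expression import correlation_matrix, mutual_rank

    rng = np.random.default_rng(seed)
    expr = ExpressionMatrix(
        values=pd.DataFrame(
            rng.normal(size=(n_genes, 12)),
            index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        )
    )
    return mutual_rank(correlation_matrix(expr))


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 8 MR tables, bitscores, planted truth."""
    collection, truth, cfg = default_collection(seed=17)
    return collection, truth, cfg


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced fixture config for cheaper per-module tests."""
    return FixtureConfig(seed=7, n_genes=80, n_runs=24,
                         n_low_expression_genes=6)
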