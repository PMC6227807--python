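import numpy as np
import pytest

from entroscape.io import BinaryMatrix, ExpressionMatrix


@pytest.fixture
def make_binary_matrix():
    """Build a single- or multi-population BinaryMatrix from call arrays."""

    def _make(calls, population="X"):
        calls = np.asarray(calls)
        n, g = calls.shape
        pops = [population] * n if isinstance(population, str) else list(population)
        return BinaryMatrix(
            calls=calls,
            cell_ids=[f"c{i}" for i in range(n)],
            gene_ids=[f"g{j}" for j in range(g)],
            population=pops,
        )

    return _make


@pytest.fixture
def small_expression_matrix():
    return ExpressionMatrix(
        values=np.array([[0.0, 3.2], [1.5, 0.0], [2.0, 2.5]]),
        cell_ids=["c0", "c1", "c2"],
        gene_ids=["gA", "gB"],
        population=["P", "P", "Q"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
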