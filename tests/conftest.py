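import numpy as np
import pytest

from ncis.io import ExpressionMatrix, GeneNetwork


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    values = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    return ExpressionMatrix(["ga", "gb", "gc"], ["s1", "s2"], values)


@pytest.fixture
def chain_network() -> GeneNetwork:
    # g1 -> g2, g1 -> g3
    return GeneNetwork.from_edges(["g1", "g2", "g3"], [(0, 1), (0, 2)])


def planted_blocks(means: np.ndarray, gene_labels: np.ndarray,
                   sample_labels: np.ndarray) -> np.ndarray:
    """Noiseless block matrix with X[i, j] = means[gene_labels[i], sample_labels[j]]."""
    return means[gene_labels][:, sample_labels]


@pytest.fixture
def planted_2x2():
    """Well-separated noiseless 2 gene blocks x 2 sample blocks."""
    means = np.array([[1.0, 5.0], [6.0, 2.0]])
    gl = np.repeat([0, 1], [14, 10])
    sl = np.repeat([0, 1], [9, 7])
    return planted_blocks(means, gl, sl), gl, sl
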