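import numpy as np
import pytest

from rcmpm.contact_geometry import ContactMap
from rcmpm.graph_builder import build_contact_graph
from rcmpm.io_formats import MSA, ResidueChain, ScoreMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_chain():
    """Four residues on a line, 3.8 A apart."""
    coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]], dtype=float)
    return ResidueChain("ACGW", coords)


@pytest.fixture
def coupled_msa():
    """Hand-built 4-row MSA whose columns 0 and 1 are perfectly correlated."""
    return MSA(["AW", "AW", "CY", "CY"])


def random_contact_map(L: int, rng: np.random.Generator, density: float = 0.3) -> ContactMap:
    upper = (rng.random((L, L)) < density).astype(np.int8)
    labels = np.triu(upper, 1)
    labels = labels + labels.T
    np.fill_diagonal(labels, 1)
    return ContactMap(labels)


def random_symmetric_scores(L: int, rng: np.random.Generator) -> ScoreMatrix:
    m = rng.random((L, L))
    return ScoreMatrix((m + m.T) / 2)


def random_graph(L: int, rng: np.random.Generator):
    return build_contact_graph(random_symmetric_scores(L, rng), edge_threshold=0.5)
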