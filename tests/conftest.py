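import numpy as np
import pandas as pd
import pytest

from seedgo.io_formats import AnnotationMap, GeneStatTable, Interactome
import networkx as nx


@pytest.fixture
def toy_table():
    """Six genes, four DEGs (two up, two down), one boundary q."""
    df = pd.DataFrame(
        {
            "gene_id": ["A", "B", "C", "D", "E", "F"],
            "log2fc": [1.5, 0.5, -2.0, -0.5, 0.1, -0.1],
            "p_value": [0.001, 0.002, 0.003, 0.004, 0.2, 0.5],
            "q_value": [0.01, 0.02, 0.03, 0.04, 0.05, 0.6],
        }
    )
    return GeneStatTable("5uM_48h", df)


@pytest.fixture
def toy_net():
    g = nx.Graph()
    g.add_edge("S", "A", score=0.9)
    g.add_edge("S", "B", score=0.3)
    g.add_edge("A", "B", score=0.95)
    return Interactome(g, seed_node="S")


@pytest.fixture
def toy_annot():
    return AnnotationMap(
        {
            "GO:0000001": {"A", "B", "C", "D"},
            "GO:0000002": {"C", "D", "E"},
            "GO:0000003": {"F", "G"},
        },
        {
            "GO:0000001": ("process one", "P"),
            "GO:0000002": ("process two", "P"),
            "GO:0000003": ("process three", "P"),
        },
    )


@pytest.fixture
def small_cfg():
    """A scaled-down generator config for fast structural tests."""
    from seedgo.synthetic import SyntheticConfig

    return SyntheticConfig(
        rng_seed=11,
        n_genes=300,
        n_terms=30,
        term_size_range=(5, 60),
        n_parents=5,
        n_planted_terms=3,
        seed_degree=80,
        n_background_edges=400,
        min_planted_overlap=8,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
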