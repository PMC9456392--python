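import networkx as nx
import numpy as np
import pytest

from synergraph import (
    BoostConfig,
    WalkConfig,
    build_walk_corpus,
    cross_validate,
    feature_table,
    make_synergy_study,
    train_skipgram,
)


@pytest.fixture
def star5() -> nx.Graph:
    """K_{1,4}: center 'c' with leaves 'l1'..'l4'."""
    g = nx.Graph()
    for i in range(1, 5):
        g.add_edge("c", f"l{i}")
    return g


@pytest.fixture
def barbell6() -> nx.Graph:
    """Two triangles joined by one edge; ('a1','b1') etc. are mirror pairs."""
    g = nx.Graph()
    g.add_edges_from([("a1", "a2"), ("a1", "a3"), ("a2", "a3")])
    g.add_edges_from([("b1", "b2"), ("b1", "b3"), ("b2", "b3")])
    g.add_edge("a3", "b3")
    return g


@pytest.fixture
def path3() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


# --- small but complete synthetic study, shared by the cheaper pipeline tests
SMALL_STUDY_KW = dict(
    n_drugs=10, n_cells=4, n_records=400, seed=1, n_motifs=6, motif_size=6
)


@pytest.fixture(scope="session")
def small_study():
    return make_synergy_study(**SMALL_STUDY_KW)


@pytest.fixture(scope="session")
def small_embedding(small_study):
    corpus = build_walk_corpus(small_study.network, WalkConfig(seed=1))
    return train_skipgram(corpus, d=32, epochs=3, seed=1)


@pytest.fixture(scope="session")
def small_table(small_study, small_embedding):
    return feature_table(
        small_embedding, small_study.drug_map, small_study.cell_map,
        small_study.records,
    )


# --- the default-scale study used by the heavyweight end-to-end checks
@pytest.fixture(scope="session")
def default_study():
    return make_synergy_study(seed=1)


@pytest.fixture(scope="session")
def default_corpus(default_study):
    return build_walk_corpus(default_study.network, WalkConfig(seed=1))


@pytest.fixture(scope="session")
def default_embedding(default_corpus):
    return train_skipgram(default_corpus, d=64, seed=1)


@pytest.fixture(scope="session")
def default_table(default_study, default_embedding):
    return feature_table(
        default_embedding, default_study.drug_map, default_study.cell_map,
        default_study.records,
    )


@pytest.fixture(scope="session")
def default_cv(default_table):
    return cross_validate(default_table, folds=5, repeats=1, cfg=BoostConfig(seed=1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
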