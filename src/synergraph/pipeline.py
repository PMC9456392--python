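"""Convenience orchestration: network → embeddings → features → evaluation.

These helpers chain the stage modules with consistent seeding; the CLI and
the evaluation scripts are thin wrappers around them.
"""

from __future__ import annotations

import logging

from .featurize import FeatureTable, assemble_pairs, entity_features
from .model_eval import BoostConfig, CVResult, cross_validate
from .netio import AssociationMap, PPINetwork, SynergyRecord
from .skipgram import EmbeddingMatrix, train_skipgram
from .struc2vec import (
    WalkConfig,
    build_multilayer_graph,
    generate_walks,
    structural_distances,
)
from .synthetic import SyntheticStudy

logger = logging.getLogger(__name__)


def build_walk_corpus(g: PPINetwork, walk_cfg: WalkConfig) -> list[list[str]]:
    """Structural distances → multilayer graph → biased walk corpus."""
    dist = structural_distances(g, k_max=walk_cfg.k_max)
    mlg = build_multilayer_graph(dist)
    return generate_walks(mlg, walk_cfg)


def embed_network(
    g: PPINetwork,
    walk_cfg: WalkConfig | None = None,
    dim: int = 64,
    window: int = 5,
    epochs: int = 5,
    corpus: list[list[str]] | None = None,
) -> EmbeddingMatrix:
    """Structural embedding of every network node.

    A precomputed walk ``corpus`` may be passed to amortise walk generation
    across embedding dimensions.
    """
    walk_cfg = walk_cfg or WalkConfig()
    if corpus is None:
        corpus = build_walk_corpus(g, walk_cfg)
    return train_skipgram(
        corpus, d=dim, window=window, epochs=epochs, seed=walk_cfg.seed
    )


def feature_table(
    emb: EmbeddingMatrix,
    drug_map: AssociationMap,
    cell_map: AssociationMap,
    records: list[SynergyRecord],
    symmetrize: bool = False,
) -> FeatureTable:
    """Pool embeddings into entity features and assemble labelled rows.

    Unsymmetrized by default: cross-validation symmetrizes training folds
    itself, after splitting.
    """
    return assemble_pairs(
        records,
        drug_feats=entity_features(emb, drug_map),
        cell_feats=entity_features(emb, cell_map),
        tissue=cell_map.tissue,
        symmetrize=symmetrize,
    )


def run_study(
    study: SyntheticStudy,
    dim: int = 64,
    walk_cfg: WalkConfig | None = None,
    boost_cfg: BoostConfig | None = None,
    folds: int = 5,
    repeats: int = 5,
    window: int = 5,
    epochs: int = 5,
) -> tuple[CVResult, EmbeddingMatrix, FeatureTable]:
    """End-to-end evaluation of a synthetic study."""
    walk_cfg = walk_cfg or WalkConfig(seed=study.seed)
    boost_cfg = boost_cfg or BoostConfig(seed=study.seed)
    emb = embed_network(study.network, walk_cfg, dim=dim, window=window, epochs=epochs)
    table = feature_table(emb, study.drug_map, study.cell_map, study.records)
    cvres = cross_validate(table, folds=folds, repeats=repeats, cfg=boost_cfg)
    return cvres, emb, table
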