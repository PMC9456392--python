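"""Pooling protein embeddings into drug/cell-line features and pair rows.

A drug (or cell line) is represented by the element-wise arithmetic mean of
the embedding vectors of its target proteins::

    D_i = (P_1 + P_2 + ... + P_n) / n

A drug–drug–cell-line sample is the concatenation
``[feat(drug_a) | feat(drug_b) | feat(cell)]`` of width ``3 d`` (192 for the
default 64-dimensional embeddings), labelled by the sign of its synergy score.

Synergy is order-free but concatenation is not, so training rows may be
*symmetrized*: each record contributes both orderings (A, B, C) and (B, A, C)
with the same label.  Cross-validation symmetrizes only after fold splitting
so both copies of a record stay on the same side of the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netio import AssociationMap, SynergyRecord
from .skipgram import EmbeddingMatrix

logger = logging.getLogger(__name__)

META_COLUMNS = ("drug_a", "drug_b", "cell", "tissue")


def entity_feature(emb: EmbeddingMatrix, targets) -> np.ndarray:
    """Element-wise mean of the embedding vectors of *targets*.

    Raises on an empty target set (such entities must be filtered upstream)
    or on a target without a vector.
    """
    targets = sorted(targets)
    if not targets:
        raise ValueError("entity has no targets to pool")
    missing = [t for t in targets if t not in emb]
    if missing:
        raise KeyError(f"targets without embedding vectors: {missing[:5]}")
    return emb.take(targets).mean(axis=0)


def entity_features(emb: EmbeddingMatrix, amap: AssociationMap) -> dict[str, np.ndarray]:
    """Pooled feature vector for every entity in an association map."""
    return {e: entity_feature(emb, amap.targets[e]) for e in amap.entities}


@dataclass
class FeatureTable:
    """Labelled concatenated features, one row per retained synergy record."""

    X: np.ndarray                 # (n, 3 d)
    y: np.ndarray                 # (n,) in {0, 1}
    meta: pd.DataFrame            # drug_a, drug_b, cell, tissue per row
    d: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.X.shape[1] != 3 * self.d:
            raise ValueError(f"row width {self.X.shape[1]} != 3*d = {3 * self.d}")
        if not np.isfinite(self.X).all():
            raise ValueError("feature rows must be finite")

    def __len__(self) -> int:
        return self.X.shape[0]

    def swapped(self) -> np.ndarray:
        """Rows with the two drug blocks exchanged: (B, A, C) ordering."""
        d = self.d
        return np.concatenate(
            [self.X[:, d:2 * d], self.X[:, :d], self.X[:, 2 * d:]], axis=1
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{i:03d}" for i in range(3 * self.d)]
        df = pd.concat(
            [self.meta.reset_index(drop=True),
             pd.DataFrame(self.X, columns=cols)],
            axis=1,
        )
        df["label"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        if len(feat_cols) % 3:
            raise ValueError("feature column count is not a multiple of 3")
        meta = df[[c for c in META_COLUMNS if c in df.columns]].copy()
        if "tissue" not in meta.columns:
            meta["tissue"] = ""
        return cls(
            X=df[feat_cols].to_numpy(dtype=float),
            y=df["label"].to_numpy(dtype=int),
            meta=meta,
            d=len(feat_cols) // 3,
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))


def assemble_pairs(
    records: list[SynergyRecord],
    drug_feats: dict[str, np.ndarray],
    cell_feats: dict[str, np.ndarray],
    tissue: dict[str, str] | None = None,
    symmetrize: bool = True,
) -> FeatureTable:
    """Build the labelled feature table for a list of synergy records.

    Records whose drugs or cell line have no feature vector are dropped and
    counted in ``n_dropped``.  With ``symmetrize`` on, each record contributes
    both drug orderings (intended for a table used wholesale for training; for
    cross-validation build an unsymmetrized table and let the splitter
    symmetrize the training folds).
    """
    tissue = tissue or {}
    if not drug_feats or not cell_feats:
        raise ValueError("no synergy record could be featurized")
    d = len(next(iter(drug_feats.values())))
    rows: list[np.ndarray] = []
    labels: list[int] = []
    meta: list[tuple[str, str, str, str]] = []
    n_dropped = 0
    conflicts: set[tuple[str, str, str]] = set()
    seen: dict[tuple[str, str, str], int] = {}
    for rec in records:
        fa = drug_feats.get(rec.drug_a)
        fb = drug_feats.get(rec.drug_b)
        fc = cell_feats.get(rec.cell)
        if fa is None or fb is None or fc is None:
            n_dropped += 1
            continue
        key = (*sorted((rec.drug_a, rec.drug_b)), rec.cell)
        if key in seen and seen[key] != rec.label:
            conflicts.add(key)
        seen[key] = rec.label
        orderings = [(rec.drug_a, fa, rec.drug_b, fb)]
        if symmetrize:
            orderings.append((rec.drug_b, fb, rec.drug_a, fa))
        for name1, f1, name2, f2 in orderings:
            rows.append(np.concatenate([f1, f2, fc]))
            labels.append(rec.label)
            meta.append((name1, name2, rec.cell, tissue.get(rec.cell, "")))
    if not rows:
        raise ValueError("no synergy record could be featurized")
    if n_dropped:
        logger.warning("assemble_pairs: dropped %d unfeaturizable records", n_dropped)
    if conflicts:
        logger.warning(
            "assemble_pairs: %d duplicate combinations carry conflicting labels; "
            "keeping all rows", len(conflicts),
        )
    return FeatureTable(
        X=np.asarray(rows, dtype=float),
        y=np.asarray(labels, dtype=int),
        meta=pd.DataFrame(meta, columns=list(META_COLUMNS)),
        d=d,
        n_dropped=n_dropped,
    )
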