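"""Readers and writers for the pipeline's plain-text inputs and outputs.

All on-disk formats are deliberately simple text:

* **edge list** — two whitespace/tab-delimited protein identifiers per line;
  ``#`` comments and blank lines ignored.  Loaded as a simple undirected
  :class:`networkx.Graph`; self-loops, duplicate edges (in either orientation)
  and isolated nodes are dropped, with counts logged.
* **association table** — ``entity<TAB>protein[<TAB>tissue]`` rows mapping a
  drug or cell line to one of its target proteins.  The optional third column
  carries a tissue label (cell lines only).
* **synergy table** — a delimited file with header columns ``drug_a, drug_b,
  cell, score``.  Rows are labelled by the sign of the score: positive scores
  are synergistic (label 1), negative scores antagonistic (label 0), and
  zero-score rows are dropped because neither class is defined for them.
* **embedding file** — header ``n d`` followed by one ``id v1 ... vd`` row per
  node, round-tripping to at least six significant digits.

Identifier matching is exact and case-sensitive throughout; no gene-symbol
normalisation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import networkx as nx
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .skipgram import EmbeddingMatrix

logger = logging.getLogger(__name__)

#: The PPI network is represented directly as a simple undirected
#: :class:`networkx.Graph` with string node identifiers.
PPINetwork = nx.Graph

SYNERGY_COLUMNS = ("drug_a", "drug_b", "cell", "score")


class ParseError(ValueError):
    """A malformed line or header in one of the text inputs."""


@dataclass
class AssociationMap:
    """Entity (drug or cell line) → set of target proteins, plus optional tissue.

    Protein sets are guaranteed non-empty and restricted to the nodes of the
    network they were loaded against.
    """

    targets: dict[str, set[str]] = field(default_factory=dict)
    tissue: dict[str, str] = field(default_factory=dict)

    def __contains__(self, entity: str) -> bool:
        return entity in self.targets

    def __getitem__(self, entity: str) -> set[str]:
        return self.targets[entity]

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def entities(self) -> list[str]:
        return sorted(self.targets)


@dataclass(frozen=True)
class SynergyRecord:
    """One drug–drug–cell-line measurement, labelled by the sign of its score."""

    drug_a: str
    drug_b: str
    cell: str
    score: float
    label: int

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError(f"self-combination {self.drug_a!r} is not a record")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def read_edge_list(path: str | Path) -> PPINetwork:
    """Load an undirected simple graph from a two-column edge list.

    Duplicate lines and reversed duplicates collapse to a single edge.
    Self-loops are discarded, and nodes left with degree zero afterwards are
    removed (the structural-distance machinery divides by node degree, which
    must be ≥ 1).  Counts of dropped items are logged at INFO level.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ParseError
        If a non-comment line has fewer than two tokens.
    """
    g: PPINetwork = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}: line {lineno}: expected at least 2 tokens")
            u, v = tokens[0], tokens[1]
            g.add_node(u)
            g.add_node(v)
            if u == v:
                n_self += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    logger.info(
        "read_edge_list(%s): %d nodes, %d edges (dropped %d self-loops, "
        "%d duplicate edges, %d isolated nodes)",
        path, g.number_of_nodes(), g.number_of_edges(), n_self, n_dup, len(isolated),
    )
    return g


def read_associations(path: str | Path, universe: PPINetwork) -> AssociationMap:
    """Load an entity→protein association table filtered to *universe* nodes.

    Entities whose entire target set falls outside the network are excluded
    with a warning.  An association map with no surviving entities is a hard
    error: nothing downstream could be featurized.
    """
    raw_targets: dict[str, set[str]] = {}
    tissue: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}: line {lineno}: expected at least 2 tokens")
            entity, protein = tokens[0], tokens[1]
            raw_targets.setdefault(entity, set()).add(protein)
            if len(tokens) >= 3:
                tissue[entity] = tokens[2]

    amap = AssociationMap()
    nodes = set(universe.nodes)
    dropped: list[str] = []
    for entity, proteins in raw_targets.items():
        kept = proteins & nodes
        if kept:
            amap.targets[entity] = kept
            if entity in tissue:
                amap.tissue[entity] = tissue[entity]
        else:
            dropped.append(entity)
    if dropped:
        logger.warning(
            "read_associations(%s): excluded %d entities with no targets in the "
            "network: %s", path, len(dropped), ", ".join(sorted(dropped)[:10]),
        )
    if not amap.targets:
        raise ParseError(f"{path}: no entity has any target in the network")
    return amap


def read_synergy(path: str | Path) -> list[SynergyRecord]:
    """Load a synergy table and assign binary labels by the sign of the score.

    Rows with score exactly zero are dropped (and counted); rows pairing a
    drug with itself are dropped with a warning.  Row order is preserved.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in SYNERGY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() & df["score"].notna() | df["score"].isna()
    if bad.any():
        lineno = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: line {lineno}: non-numeric score {df['score'][bad.idxmax()]!r}")

    records: list[SynergyRecord] = []
    n_zero = n_self = 0
    for row, score in zip(df.itertuples(index=False), scores):
        if score == 0.0:
            n_zero += 1
            continue
        if str(row.drug_a) == str(row.drug_b):
            n_self += 1
            continue
        records.append(
            SynergyRecord(
                drug_a=str(row.drug_a),
                drug_b=str(row.drug_b),
                cell=str(row.cell),
                score=float(score),
                label=1 if score > 0 else 0,
            )
        )
    if n_zero or n_self:
        logger.warning(
            "read_synergy(%s): dropped %d zero-score rows and %d self-pair rows",
            path, n_zero, n_self,
        )
    logger.info(
        "read_synergy(%s): %d records (%d positive, %d negative)",
        path, len(records), sum(r.label for r in records),
        sum(1 - r.label for r in records),
    )
    return records


def write_embeddings(emb: "EmbeddingMatrix", path: str | Path) -> None:
    """Write an embedding matrix as text: header ``n d`` then one row per node."""
    vectors = np.asarray(emb.vectors, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(emb.ids)} {emb.d}\n")
        for node, vec in zip(emb.ids, vectors):
            fh.write(node + " " + " ".join(f"{x:.10g}" for x in vec) + "\n")


def read_embeddings(path: str | Path) -> "EmbeddingMatrix":
    """Read an embedding matrix written by :func:`write_embeddings`."""
    from .skipgram import EmbeddingMatrix

    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}: malformed header {header!r}")
        n, d = int(header[0]), int(header[1])
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != d + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {d + 1} tokens, got {len(tokens)}"
                )
            ids.append(tokens[0])
            rows.append([float(t) for t in tokens[1:]])
    if len(ids) != n:
        raise ParseError(f"{path}: header promised {n} rows, found {len(ids)}")
    vectors = np.asarray(rows, dtype=float).reshape(len(ids), d)
    return EmbeddingMatrix(ids=ids, vectors=vectors)


def write_edge_list(g: PPINetwork, path: str | Path) -> None:
    """Write a graph back out as a sorted two-column edge list."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\n")


def write_associations(amap: AssociationMap, path: str | Path) -> None:
    """Write an association map as entity/protein(/tissue) rows."""
    with open(path, "w") as fh:
        for entity in amap.entities:
            tis = amap.tissue.get(entity)
            for protein in sorted(amap.targets[entity]):
                if tis is None:
                    fh.write(f"{entity}\t{protein}\n")
                else:
                    fh.write(f"{entity}\t{protein}\t{tis}\n")


def write_synergy(records: Iterable[SynergyRecord], path: str | Path) -> None:
    """Write synergy records as a CSV with the canonical header."""
    df = pd.DataFrame(
        [(r.drug_a, r.drug_b, r.cell, r.score) for r in records],
        columns=list(SYNERGY_COLUMNS),
    )
    df.to_csv(path, index=False)
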