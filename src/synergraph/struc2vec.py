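"""Structural node similarity, the multilayer walk graph, and biased walks.

The embedding substrate is built in three steps:

1.  **Structural distances.**  For every node ``u`` and hop distance ``k``,
    take the *ring* ``R_k(u)`` — the nodes at exactly ``k`` hops — and its
    ascending degree sequence.  The layer-``k`` structural distance between a
    node pair accumulates dynamic-time-warping (DTW) costs between their ring
    degree sequences::

        f_k(u, v) = f_{k-1}(u, v) + DTW(s(R_k(u)), s(R_k(v))),   f_{-1} = 0

    with element cost ``g(x, y) = max(x, y)/min(x, y) - 1``, so that equal
    degrees cost nothing and the cost is scale-sensitive (degrees 1 vs 2 are
    further apart than 101 vs 102).

2.  **Multilayer graph.**  Layer ``k`` is a complete weighted graph over the
    node pairs retained at that depth, with intra-layer weight
    ``w_k(u,v) = exp(-f_k(u,v))``.  Each node is also connected to its copy in
    the adjacent layers: the upward weight is ``log(Γ_k(u) + e)`` where
    ``Γ_k(u)`` counts u's intra-layer edges heavier than the layer's mean edge
    weight (i.e. how many *unusually similar* partners u has at this depth),
    and the downward weight is 1.

3.  **Biased walks.**  A walker starts every walk at layer 0.  With
    probability ``q`` it moves within the current layer (to ``v`` with
    probability ``exp(-f_k(u,v)) / Z_k(u)``) and emits the node it lands on;
    with probability ``1 - q`` it switches layer (up/down proportional to the
    inter-layer weights) without emitting.  The walk ends once ``walk_length``
    tokens have been emitted.

Pairs whose rings empty at some depth simply do not exist in higher layers;
a walker stranded without same-layer partners is forced downward (layer 0 is
always complete, so this never loops forever).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

from .netio import PPINetwork

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ring degree sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingProfile:
    """Ascending degree sequence of the nodes at exactly ``k`` hops from a node."""

    node: str
    k: int
    degrees: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.degrees)


def _rings_up_to(g: PPINetwork, u: str, k_max: int) -> list[np.ndarray]:
    """Degree sequences of rings 0..k_max around *u* from one truncated BFS."""
    dist = nx.single_source_shortest_path_length(g, u, cutoff=k_max)
    buckets: list[list[int]] = [[] for _ in range(k_max + 1)]
    for v, k in dist.items():
        buckets[k].append(g.degree(v))
    return [np.sort(np.asarray(b, dtype=np.float64)) for b in buckets]


def ring_degree_sequence(g: PPINetwork, u: str, k: int) -> RingProfile:
    """Sorted degrees of the nodes at exactly hop distance *k* from *u*.

    The ring at ``k = 0`` is the node itself, so its profile is ``[deg(u)]``.
    The profile is empty when *k* exceeds the eccentricity of *u*.
    """
    if u not in g:
        raise KeyError(f"node {u!r} not in graph")
    if k < 0:
        raise ValueError("hop distance k must be >= 0")
    degs = _rings_up_to(g, u, k)[k]
    return RingProfile(node=u, k=k, degrees=tuple(int(d) for d in degs))


# ---------------------------------------------------------------------------
# DTW on degree sequences
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dtw_dp(cost: np.ndarray) -> float:
    # Full dynamic program over the pairwise cost matrix; no windowing.
    n, m = cost.shape
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = best + cost[i, j]
    return acc[n - 1, m - 1]


def dtw_degree_distance(a, b) -> float:
    """Minimal DTW alignment cost between two degree sequences.

    Element cost is ``max(x, y)/min(x, y) - 1``: zero for equal degrees,
    relative otherwise.  Symmetric, non-negative, and zero iff the sequences
    are identical.  Degrees must be ≥ 1 (the cost divides by the minimum).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("degree sequences must be non-empty")
    if (a < 1).any() or (b < 1).any():
        raise ValueError("degrees must be >= 1")
    cost = np.maximum.outer(a, b) / np.minimum.outer(a, b) - 1.0
    return float(_dtw_dp(cost))


# ---------------------------------------------------------------------------
# Structural distance table
# ---------------------------------------------------------------------------

@dataclass
class StructuralDistanceTable:
    """Accumulated structural distances ``f_k(u, v)`` for layers 0..k_max.

    ``layers[k]`` maps a sorted node pair to ``f_k``; a pair is present at
    layer *k* only if both rings at *k* are non-empty (rings are contiguous,
    so the pair set shrinks with *k*).  ``present[k]`` is the set of nodes
    whose own ring at *k* is non-empty.
    """

    k_max: int
    nodes: list[str]
    layers: list[dict[tuple[str, str], float]]
    present: list[set[str]]

    def f(self, k: int, u: str, v: str) -> float:
        return self.layers[k][(u, v) if u <= v else (v, u)]


def structural_distances(
    g: PPINetwork,
    k_max: int = 4,
    max_degree_ratio: float | None = None,
) -> StructuralDistanceTable:
    """All-pairs accumulated structural distances up to *k_max* hops.

    Each layer is complete over the retained pairs.  ``max_degree_ratio`` is
    an optional approximation for large graphs (off by default): when set,
    only pairs whose degrees differ by at most that multiplicative factor are
    compared at all.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    nodes = sorted(g.nodes)
    rings = {u: _rings_up_to(g, u, k_max) for u in nodes}
    present = [
        {u for u in nodes if rings[u][k].size > 0} for k in range(k_max + 1)
    ]

    def admit(u: str, v: str) -> bool:
        if max_degree_ratio is None:
            return True
        du, dv = g.degree(u), g.degree(v)
        return max(du, dv) / min(du, dv) <= max_degree_ratio

    layers: list[dict[tuple[str, str], float]] = []
    base = {
        (u, v): 0.0
        for u, v in itertools.combinations(nodes, 2)
        if admit(u, v)
    }
    prev = base
    for k in range(k_max + 1):
        cur: dict[tuple[str, str], float] = {}
        pres = present[k]
        for (u, v), f_prev in prev.items():
            if u in pres and v in pres:
                cur[(u, v)] = f_prev + dtw_degree_distance(rings[u][k], rings[v][k])
        layers.append(cur)
        prev = cur
    logger.info(
        "structural_distances: %d nodes, %d layers, %s pairs per layer",
        len(nodes), k_max + 1, [len(la) for la in layers],
    )
    return StructuralDistanceTable(
        k_max=k_max, nodes=nodes, layers=layers, present=present
    )


# ---------------------------------------------------------------------------
# Multilayer graph
# ---------------------------------------------------------------------------

@dataclass
class _LayerNode:
    """Per-node state within one layer: partners and sampling tables."""

    partners: np.ndarray        # int indices into MultilayerGraph.nodes
    weights: np.ndarray         # w_k(u, v) = exp(-f_k(u, v))
    z: float                    # Z_k(u) = sum of weights
    cumprob: np.ndarray         # cumulative within-layer transition probs
    gamma: int                  # edges at u heavier than the layer mean
    up_weight: float            # log(gamma + e)


@dataclass
class MultilayerGraph:
    """The weighted multilayer graph the biased random walk runs on."""

    k_max: int
    nodes: list[str]
    index: dict[str, int] = field(repr=False)
    layers: list[dict[int, _LayerNode]] = field(repr=False)
    top_layer: np.ndarray = field(repr=False)  # highest layer holding each node

    def layer_node(self, k: int, u: str) -> _LayerNode:
        return self.layers[k][self.index[u]]


def build_multilayer_graph(dist: StructuralDistanceTable) -> MultilayerGraph:
    """Assemble intra- and inter-layer weights from a distance table.

    Intra-layer weights are ``exp(-f_k)``; the per-node upward weight is
    ``log(Γ_k(u) + e)`` (≥ 1, since ``Γ ≥ 0``), the downward weight is the
    constant 1 and is therefore not stored.
    """
    if not any(dist.layers):
        raise ValueError("distance table has no pairs")
    nodes = dist.nodes
    index = {u: i for i, u in enumerate(nodes)}
    layers: list[dict[int, _LayerNode]] = []
    top_layer = np.zeros(len(nodes), dtype=np.int64)

    for k in range(dist.k_max + 1):
        pairs = dist.layers[k]
        adj: dict[int, list[tuple[int, float]]] = {
            index[u]: [] for u in dist.present[k]
        }
        if pairs:
            mean_w = float(np.mean([np.exp(-f) for f in pairs.values()]))
        else:
            mean_w = 0.0
        for (u, v), f in pairs.items():
            w = float(np.exp(-f))
            adj[index[u]].append((index[v], w))
            adj[index[v]].append((index[u], w))
        layer: dict[int, _LayerNode] = {}
        for i, nbrs in adj.items():
            nbrs.sort()
            partners = np.asarray([j for j, _ in nbrs], dtype=np.int64)
            weights = np.asarray([w for _, w in nbrs], dtype=np.float64)
            z = float(weights.sum())
            cumprob = (
                np.cumsum(weights) / z if z > 0 else np.empty(0, dtype=np.float64)
            )
            gamma = int((weights > mean_w).sum())
            layer[i] = _LayerNode(
                partners=partners,
                weights=weights,
                z=z,
                cumprob=cumprob,
                gamma=gamma,
                up_weight=float(np.log(gamma + np.e)),
            )
            top_layer[i] = k
        layers.append(layer)
    return MultilayerGraph(
        k_max=dist.k_max, nodes=nodes, index=index, layers=layers,
        top_layer=top_layer,
    )


# ---------------------------------------------------------------------------
# Biased random walks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkConfig:
    """Walk-generation settings (defaults follow the embedding's standard setup)."""

    walks_per_node: int = 20
    walk_length: int = 80
    k_max: int = 4
    stay_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_node <= 0 or self.walk_length <= 0 or self.k_max < 0:
            raise ValueError("walk counts and lengths must be positive")
        if not 0.0 < self.stay_prob < 1.0:
            raise ValueError("stay_prob must be strictly between 0 and 1")


def sample_walk(
    mlg: MultilayerGraph,
    start: str,
    cfg: WalkConfig,
    rng: np.random.Generator,
) -> list[str]:
    """One biased walk starting at *start* in layer 0.

    Within-layer moves emit the node landed on; layer switches emit nothing.
    ``walk_length`` counts emitted tokens (the start node counts as the first).
    """
    i = mlg.index[start]  # KeyError for unknown nodes
    if i not in mlg.layers[0]:
        raise KeyError(f"start node {start!r} missing from layer 0")
    k_top_cap = mlg.k_max
    k = 0
    out = [start]
    while len(out) < cfg.walk_length:
        ln = mlg.layers[k].get(i)
        if ln is None or ln.partners.size == 0:
            # stranded: no same-layer partners -> forced downward switch
            if k > 0:
                k -= 1
                continue
            break  # single-node layer 0: nowhere to go
        if rng.random() < cfg.stay_prob:
            j = int(np.searchsorted(ln.cumprob, rng.random(), side="right"))
            j = min(j, ln.partners.size - 1)  # guard fp edge at 1.0
            i = int(ln.partners[j])
            out.append(mlg.nodes[i])
        else:
            top = min(int(mlg.top_layer[i]), k_top_cap)
            if top == 0:
                continue  # no other layer exists for this node
            if k == 0:
                k = 1  # no layer below: forced up
            elif k >= top:
                k -= 1  # no layer above: forced down
            else:
                p_up = ln.up_weight / (ln.up_weight + 1.0)
                k += 1 if rng.random() < p_up else -1
    return out


def layer_switch_probability(mlg: MultilayerGraph, k: int, u: str) -> tuple[float, float]:
    """(up, down) switch probabilities for node *u* at layer *k*.

    At layer 0 the walk must go up; at the node's top layer it must go down.
    """
    ln = mlg.layer_node(k, u)
    top = min(int(mlg.top_layer[mlg.index[u]]), mlg.k_max)
    if k == 0:
        return (1.0, 0.0) if top > 0 else (0.0, 0.0)
    if k >= top:
        return (0.0, 1.0)
    p_up = ln.up_weight / (ln.up_weight + 1.0)
    return (p_up, 1.0 - p_up)


def generate_walks(mlg: MultilayerGraph, cfg: WalkConfig) -> list[list[str]]:
    """Full walk corpus: ``walks_per_node`` walks from every node.

    Deterministic for a fixed seed: the node visit order is reshuffled each
    epoch, and each walk draws from its own substream derived from
    ``(seed, epoch, node index)`` so corpora are stable under parallel or
    out-of-order generation.
    """
    n = len(mlg.nodes)
    walks: list[list[str]] = []
    for epoch in range(cfg.walks_per_node):
        order_rng = np.random.default_rng((cfg.seed, 7919, epoch))
        for i in order_rng.permutation(n):
            walk_rng = np.random.default_rng((cfg.seed, epoch, int(i)))
            walks.append(sample_walk(mlg, mlg.nodes[int(i)], cfg, walk_rng))
    return walks


def write_walks(walks: list[list[str]], path) -> None:
    """One walk per line, whitespace-separated node ids."""
    with open(path, "w") as fh:
        for walk in walks:
            fh.write(" ".join(walk) + "\n")


def read_walks(path) -> list[list[str]]:
    with open(path) as fh:
        return [line.split() for line in fh if line.strip()]
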