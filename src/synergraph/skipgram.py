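"""Skip-Gram with negative sampling over walk corpora.

The walk corpus is treated as a collection of sentences whose "words" are
node identifiers.  Training maximises, for each (center, context) pair within
a symmetric window, the log-sigmoid score of the true context against
``negative`` samples drawn from the unigram distribution raised to 3/4 — the
standard word2vec objective.  Optimisation is plain SGD with a linearly
decaying learning rate; the inner loop is compiled with numba.

Determinism: for a fixed seed the pair order, negative draws and
initialisation are all generated from one seeded numpy Generator and the SGD
loop is single-threaded, so retraining reproduces vectors bit-identically.

Every token that occurs in the corpus receives a vector (no minimum-count
filtering): downstream pooling requires a vector for every target protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

SUPPORTED_DIMS = (32, 64, 128)


@dataclass
class EmbeddingMatrix:
    """Node id → d-dimensional real vector, with an ordered vocabulary."""

    ids: list[str]
    vectors: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be (n_ids, d)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding vectors must be finite")
        self._index = {node: i for i, node in enumerate(self.ids)}

    @property
    def d(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __getitem__(self, node: str) -> np.ndarray:
        return self.vectors[self._index[node]]

    def __len__(self) -> int:
        return len(self.ids)

    def take(self, nodes) -> np.ndarray:
        """Stack the vectors of *nodes* into an (len(nodes), d) matrix."""
        return self.vectors[[self._index[n] for n in nodes]]


@njit(cache=True)
def _sgns_epoch(centers, contexts, negatives, w_in, w_out,
                lr_start, lr_end, done, total):
    n_pairs = centers.shape[0]
    n_neg = negatives.shape[1]
    d = w_in.shape[1]
    for p in range(n_pairs):
        lr = lr_start + (lr_end - lr_start) * ((done + p) / total)
        c = centers[p]
        grad_c = np.zeros(d)
        for t in range(n_neg + 1):
            if t == 0:
                o = contexts[p]
                label = 1.0
            else:
                o = negatives[p, t - 1]
                if o == contexts[p]:
                    continue  # drawn negative collides with the true context
                label = 0.0
            x = 0.0
            for j in range(d):
                x += w_in[c, j] * w_out[o, j]
            if x > 10.0:
                x = 10.0
            elif x < -10.0:
                x = -10.0
            g = (label - 1.0 / (1.0 + np.exp(-x))) * lr
            for j in range(d):
                grad_c[j] += g * w_out[o, j]
                w_out[o, j] += g * w_in[c, j]
        for j in range(d):
            w_in[c, j] += grad_c[j]
    return done + n_pairs


def _corpus_pairs(sentences: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs within a fixed symmetric window."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for sent in sentences:
        n = sent.size
        for offset in range(1, window + 1):
            if n <= offset:
                continue
            left = sent[:-offset]
            right = sent[offset:]
            # both directions: (w_i -> w_{i+offset}) and (w_{i+offset} -> w_i)
            centers.append(left)
            contexts.append(right)
            centers.append(right)
            contexts.append(left)
    if not centers:
        raise ValueError("corpus has no co-occurring token pairs")
    return (
        np.concatenate(centers).astype(np.int64),
        np.concatenate(contexts).astype(np.int64),
    )


def train_skipgram(
    corpus: list[list[str]],
    d: int = 64,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Train node embeddings on a walk corpus.

    Parameters
    ----------
    corpus
        List of walks (sentences of node ids).  Must be non-empty.
    d
        Embedding dimension; 32, 64 and 128 are the supported choices.
    window
        Symmetric context window size.
    epochs, negative, alpha, min_alpha
        SGD schedule: passes over the pair list, negatives per positive pair,
        and the linear learning-rate decay endpoints.
    seed
        Seeds initialisation, pair shuffling and negative sampling.
    """
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("corpus is empty")
    if d not in SUPPORTED_DIMS:
        raise ValueError(f"dimension {d} unsupported; choose one of {SUPPORTED_DIMS}")
    if epochs <= 0:
        raise ValueError("epochs must be positive")

    vocab = sorted({tok for sent in corpus for tok in sent})
    index = {tok: i for i, tok in enumerate(vocab)}
    v = len(vocab)
    sentences = [
        np.asarray([index[t] for t in sent], dtype=np.int64) for sent in corpus
    ]
    centers, contexts = _corpus_pairs(sentences, window)
    n_pairs = centers.size

    counts = np.zeros(v, dtype=np.float64)
    for sent in sentences:
        np.add.at(counts, sent, 1.0)
    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(seed)
    w_in = (rng.random((v, d)) - 0.5) / d
    w_out = np.zeros((v, d), dtype=np.float64)

    total = n_pairs * epochs
    done = 0
    for _ in range(epochs):
        perm = rng.permutation(n_pairs)
        negs = np.searchsorted(
            noise_cdf, rng.random((n_pairs, negative))
        ).astype(np.int64)
        np.clip(negs, 0, v - 1, out=negs)
        done = _sgns_epoch(
            centers[perm], contexts[perm], negs,
            w_in, w_out, alpha, min_alpha, done, total,
        )
    logger.info(
        "train_skipgram: |V|=%d, d=%d, %d pairs x %d epochs", v, d, n_pairs, epochs
    )
    return EmbeddingMatrix(ids=vocab, vectors=w_in)
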