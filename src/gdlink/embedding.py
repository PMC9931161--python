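"""Node embeddings from second-order biased random walks.

The graph is walked as an untyped undirected network. A walk in progress
at node ``cur`` having just left ``prev`` steps to a neighbor ``x`` of
``cur`` with unnormalized weight

* ``1/P``  if ``x == prev``               (return),
* ``1``    if ``x`` is adjacent to prev   (triangle / stay close),
* ``1/Q``  otherwise                      (explore outward),

normalized over the neighbors of ``cur``. ``P = Q = 1`` reduces to a
uniform first-order walk and takes a fast path. The walks are then fed,
as sentences of node tokens, to a skip-gram model with negative sampling
(SGNS) trained by mini-batch SGD in numpy; training is single-threaded
and fully deterministic given the seed.

Defaults (64 dimensions, walk length 5, 10 walks per node, P = Q = 1)
target sparse biological graphs where short walks already capture the
disease neighborhoods that matter for link prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .hetgraph import HetGraph


class EmbeddingError(ValueError):
    pass


@dataclass(frozen=True)
class EmbeddingConfig:
    dimensions: int = 64
    walk_length: int = 5
    walks_per_node: int = 10
    p: float = 1.0  # return parameter
    q: float = 1.0  # in-out parameter
    window: int = 5
    epochs: int = 5
    negative: int = 5
    initial_lr: float = 0.025
    min_lr: float = 1e-4
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimensions < 2:
            raise EmbeddingError("dimensions must be >= 2")
        if self.walk_length < 2:
            raise EmbeddingError("walk_length must be >= 2")
        if self.p <= 0 or self.q <= 0:
            raise EmbeddingError("P and Q must be positive")


class EmbeddingTable:
    """Node-id -> vector mapping backed by a dense matrix."""

    def __init__(self, nodes: Sequence[str], vectors: np.ndarray):
        if len(nodes) != vectors.shape[0]:
            raise EmbeddingError("node/vector count mismatch")
        if not np.all(np.isfinite(vectors)):
            raise EmbeddingError("non-finite embedding values")
        self.nodes = list(nodes)
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self._pos = {n: i for i, n in enumerate(self.nodes)}

    def __getitem__(self, node: str) -> np.ndarray:
        try:
            return self.vectors[self._pos[node]]
        except KeyError:
            raise EmbeddingError(f"node {node!r} has no embedding") from None

    def __contains__(self, node: str) -> bool:
        return node in self._pos

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def dimensions(self) -> int:
        return self.vectors.shape[1]

    def save_word2vec(self, path: str | Path) -> None:
        """Persist in the word2vec text format (header: count dim)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.nodes)} {self.dimensions}\n")
            for node, vec in zip(self.nodes, self.vectors):
                fh.write(node + " " + " ".join(f"{x:.9g}" for x in vec) + "\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        with open(path) as fh:
            count, dim = map(int, fh.readline().split())
            nodes, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                nodes.append(parts[0])
                rows.append([float(x) for x in parts[1 : dim + 1]])
        if len(nodes) != count:
            raise EmbeddingError(f"{path}: header promised {count} rows")
        return cls(nodes, np.array(rows))


def generate_walks(g: HetGraph, cfg: EmbeddingConfig) -> list[list[str]]:
    """``walks_per_node`` biased walks from every node of the graph.

    Walks truncate early at nodes without neighbors; an isolated node
    yields length-1 walks of itself (it still enters the vocabulary and
    receives a near-random vector).
    """
    if not g.nodes:
        raise EmbeddingError("empty graph")
    rng = np.random.default_rng(cfg.seed)
    adjacency = {n: sorted(nbrs) for n, nbrs in g.adjacency().items()}
    adjacency_sets = {n: set(nbrs) for n, nbrs in adjacency.items()}
    unbiased = cfg.p == 1.0 and cfg.q == 1.0
    walks: list[list[str]] = []
    for start in sorted(g.nodes):
        for _ in range(cfg.walks_per_node):
            walk = [start]
            while len(walk) < cfg.walk_length:
                cur = walk[-1]
                nbrs = adjacency[cur]
                if not nbrs:
                    break
                if len(walk) == 1 or unbiased:
                    nxt = nbrs[rng.integers(len(nbrs))]
                else:
                    prev = walk[-2]
                    prev_adj = adjacency_sets[prev]
                    weights = np.array(
                        [
                            1.0 / cfg.p
                            if x == prev
                            else (1.0 if x in prev_adj else 1.0 / cfg.q)
                            for x in nbrs
                        ]
                    )
                    weights /= weights.sum()
                    nxt = nbrs[rng.choice(len(nbrs), p=weights)]
                walk.append(nxt)
            walks.append(walk)
    return walks


def _skipgram_pairs(
    walks: Iterable[Sequence[int]], window: int
) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for walk in walks:
        L = len(walk)
        for i in range(L):
            lo, hi = max(0, i - window), min(L, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(walk[i])
                    contexts.append(walk[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def fit_embeddings(walks: list[list[str]], cfg: EmbeddingConfig) -> EmbeddingTable:
    """Train SGNS on the walks-as-sentences corpus.

    Negative contexts are drawn from the unigram distribution raised to
    the 3/4 power, the standard choice for SGNS. Mini-batches apply
    accumulated (hogwild-style) updates via ``np.add.at``; with a fixed
    seed the result is reproducible bit-for-bit.
    """
    if not walks:
        raise EmbeddingError("no walks to train on")
    vocab = sorted({node for walk in walks for node in walk})
    if not vocab:
        raise EmbeddingError("empty vocabulary")
    index = {n: i for i, n in enumerate(vocab)}
    encoded = [[index[n] for n in walk] for walk in walks]

    counts = np.zeros(len(vocab))
    for walk in encoded:
        for tok in walk:
            counts[tok] += 1
    noise = counts**0.75
    noise /= noise.sum()

    rng = np.random.default_rng(cfg.seed)
    dim = cfg.dimensions
    W = (rng.random((len(vocab), dim)) - 0.5) / dim  # input vectors
    C = np.zeros((len(vocab), dim))  # output vectors

    centers, contexts = _skipgram_pairs(encoded, cfg.window)
    n_pairs = len(centers)
    if n_pairs == 0:
        # degenerate corpus of isolated nodes: random init is the embedding
        return EmbeddingTable(vocab, W)

    total_batches = cfg.epochs * ((n_pairs + cfg.batch_size - 1) // cfg.batch_size)
    batch_no = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            lr = max(
                cfg.min_lr,
                cfg.initial_lr * (1.0 - batch_no / max(1, total_batches)),
            )
            batch_no += 1
            ci, pi = centers[sel], contexts[sel]
            ni = rng.choice(len(vocab), size=(len(sel), cfg.negative), p=noise)
            wc = W[ci]  # (B, d)
            cp = C[pi]  # (B, d)
            cn = C[ni]  # (B, neg, d)
            g_pos = _sigmoid(np.einsum("bd,bd->b", wc, cp)) - 1.0  # (B,)
            g_neg = _sigmoid(np.einsum("bd,bnd->bn", wc, cn))  # (B, neg)
            grad_w = g_pos[:, None] * cp + np.einsum("bn,bnd->bd", g_neg, cn)
            np.add.at(W, ci, -lr * grad_w)
            np.add.at(C, pi, -lr * g_pos[:, None] * wc)
            np.add.at(
                C,
                ni.reshape(-1),
                (-lr * g_neg[..., None] * wc[:, None, :]).reshape(-1, dim),
            )
    return EmbeddingTable(vocab, W)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def pair_vector(tbl: EmbeddingTable, a: str, b: str) -> np.ndarray:
    """Element-wise sum of the two node vectors (order-independent)."""
    return tbl[a] + tbl[b]


def embed_graph(g: HetGraph, cfg: EmbeddingConfig) -> EmbeddingTable:
    """Convenience wrapper: walks + SGNS in one call."""
    return fit_embeddings(generate_walks(g, cfg), cfg)
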