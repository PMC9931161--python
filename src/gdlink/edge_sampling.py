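"""Labeled train/test edge sets for link classification.

Positives are a per-disease random holdout of gene-disease edges (removed
from the graph to form G'). Negatives are an equal number N of non-edges,
half gene-gene (uniform) and half gene-disease. The gene-disease half is
not uniform: each disease is paired with its lowest-GDPS non-associated
genes, a round-robin pass over diseases repeated until N/2 pairs are
collected. Low co-expression similarity to the known disease genes makes
a pair less likely to be a yet-unreported true association, so labeling
it negative is safer than a uniform draw.

Negative candidates are always checked against the ORIGINAL graph G, so a
held-out positive can never reappear as a negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .gdps import GdpsContext
from .hetgraph import GdEdge, GgEdge, HetGraph, gg_key, remove_edges

Pair = tuple[str, str]


class SamplingError(ValueError):
    """Infeasible sampling request (bad fraction, not enough non-edges)."""


@dataclass
class LabeledEdgeSet:
    """Balanced positive/negative node pairs with a stratified 70/30 split."""

    positives: list[Pair]
    negatives: list[Pair]
    pair_type: dict[Pair, str]  # "gd" | "gg"
    split: dict[Pair, str]  # "train" | "test"
    seed: int
    gdps: dict[Pair, float] = field(default_factory=dict)

    def pairs(self, split: str | None = None, label: int | None = None) -> list[Pair]:
        out = []
        for pair, lab in self.labeled_pairs():
            if split is not None and self.split[pair] != split:
                continue
            if label is not None and lab != label:
                continue
            out.append(pair)
        return out

    def labeled_pairs(self) -> list[tuple[Pair, int]]:
        return [(p, 1) for p in self.positives] + [(p, 0) for p in self.negatives]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tpair_type\tlabel\tsplit\tgdps\n")
            for pair, label in self.labeled_pairs():
                a, b = pair
                g = self.gdps.get(pair, "")
                g = f"{g:.10g}" if g != "" else ""
                fh.write(
                    f"{a}\t{b}\t{self.pair_type[pair]}\t{label}\t{self.split[pair]}\t{g}\n"
                )

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "LabeledEdgeSet":
        positives, negatives = [], []
        pair_type, split, gdps = {}, {}, {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["node_a", "node_b", "pair_type", "label", "split", "gdps"]
            if header != expected:
                raise SamplingError(f"{path}: unrecognized labeled-set header")
            for line in fh:
                a, b, ptype, label, sp, g = line.rstrip("\n").split("\t")
                pair = (a, b)
                (positives if label == "1" else negatives).append(pair)
                pair_type[pair] = ptype
                split[pair] = sp
                if g:
                    gdps[pair] = float(g)
        return cls(positives, negatives, pair_type, split, seed, gdps)


def _holdout_size(degree: int, fraction: float) -> int:
    """Half-up rounding of fraction*degree, but at least one edge."""
    return max(1, int(math.floor(fraction * degree + 0.5)))


def sample_positives(
    g: HetGraph, fraction: float, seed: int
) -> tuple[set[GdEdge], HetGraph]:
    """Hold out ~``fraction`` of each disease's association edges.

    Returns the held-out edge set (the positives) and G' — the input graph
    with those edges removed, nodes untouched.
    """
    if not (0.0 < fraction < 1.0):
        raise SamplingError(f"fraction {fraction} outside (0, 1)")
    rng = np.random.default_rng(seed)
    selected: set[GdEdge] = set()
    for disease in sorted(g.disease_nodes):
        genes = sorted(g.genes_of(disease))
        if not genes:
            continue
        k = min(len(genes), _holdout_size(len(genes), fraction))
        chosen = rng.choice(len(genes), size=k, replace=False)
        selected.update((genes[i], disease) for i in chosen)
    return selected, remove_edges(g, selected)


def sample_negative_gg(g: HetGraph, count: int, seed: int) -> set[GgEdge]:
    """Uniform sample of non-adjacent gene pairs (no replacement)."""
    if count < 0:
        raise SamplingError("count must be non-negative")
    if count == 0:
        return set()
    genes = sorted(g.gene_nodes)
    n = len(genes)
    total_pairs = n * (n - 1) // 2
    n_non_edges = total_pairs - len(g.gg_edges)
    if count > n_non_edges:
        raise SamplingError(
            f"requested {count} gene-gene non-edges but only {n_non_edges} exist"
        )
    rng = np.random.default_rng(seed)
    chosen: set[GgEdge] = set()
    # enumerate when the pair space is small, else rejection-sample
    if total_pairs <= 200_000:
        non_edges = [
            (genes[i], genes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if (genes[i], genes[j]) not in g.gg_edges
        ]
        idx = rng.choice(len(non_edges), size=count, replace=False)
        chosen = {non_edges[i] for i in idx}
    else:
        while len(chosen) < count:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            pair = gg_key(genes[i], genes[j])
            if pair in g.gg_edges or pair in chosen:
                continue
            chosen.add(pair)
    return chosen


def sample_negative_gd(
    g: HetGraph, g_prime: HetGraph, ctx: GdpsContext, count: int
) -> set[GdEdge]:
    """Lowest-GDPS gene-disease non-edges, round-robin over diseases.

    Diseases of G' are visited in lexicographic order; on each visit a
    disease contributes its unused non-associated gene (non-edge in the
    original G) with the smallest GDPS, ties broken by gene id. Passes
    repeat until ``count`` pairs are collected. Deterministic given
    (G, G', Z).
    """
    if count < 1:
        raise SamplingError("count must be >= 1")
    diseases = sorted(g_prime.disease_nodes)
    genes = sorted(g_prime.gene_nodes)
    score_of: dict[str, np.ndarray] = {}
    queues: dict[str, list[str]] = {}
    for d in diseases:
        prof = ctx.profile(d)
        scores = np.array(
            [
                prof[ctx.matrix.position(gene)] if gene in ctx.matrix else 0.0
                for gene in genes
            ]
        )
        candidates = [
            (scores[i], gene)
            for i, gene in enumerate(genes)
            if not g.adjacent(gene, d)
        ]
        candidates.sort()
        queues[d] = [gene for _, gene in candidates]
        score_of[d] = scores
    selected: set[GdEdge] = set()
    cursor = {d: 0 for d in diseases}
    while len(selected) < count:
        progressed = False
        for d in diseases:
            if len(selected) >= count:
                break
            q = queues[d]
            while cursor[d] < len(q):
                gene = q[cursor[d]]
                cursor[d] += 1
                pair = (gene, d)
                if pair not in selected:
                    selected.add(pair)
                    progressed = True
                    break
        if not progressed and len(selected) < count:
            raise SamplingError(
                f"only {len(selected)} gene-disease non-edges available, "
                f"{count} requested"
            )
    return selected


def make_labeled_set(
    g: HetGraph,
    fraction: float,
    train_frac: float,
    ctx: GdpsContext,
    seed: int,
) -> tuple[LabeledEdgeSet, HetGraph]:
    """Compose the three samplers into a balanced, split labeled set.

    ``ctx.graph`` is replaced internally by the freshly reduced G' so that
    GDPS (both for negative selection and the stored feature values) never
    sees the held-out edges.
    """
    if not (0.0 < train_frac < 1.0):
        raise SamplingError(f"train fraction {train_frac} outside (0, 1)")
    positives_set, g_prime = sample_positives(g, fraction, seed)
    ctx = replace(ctx, graph=g_prime)
    n = len(positives_set)
    n_gg = n // 2
    n_gd = n - n_gg
    neg_gg = sample_negative_gg(g, n_gg, seed + 1)
    neg_gd = sample_negative_gd(g, g_prime, ctx, n_gd)
    positives = sorted(positives_set)
    negatives = sorted(neg_gd) + sorted(neg_gg)
    pair_type: dict[Pair, str] = {}
    for p in positives:
        pair_type[p] = "gd"
    for p in neg_gd:
        pair_type[p] = "gd"
    for p in neg_gg:
        pair_type[p] = "gg"

    rng = np.random.default_rng(seed + 2)
    split: dict[Pair, str] = {}
    for group in (positives, negatives):
        order = rng.permutation(len(group))
        n_train = int(math.floor(train_frac * len(group) + 0.5))
        n_train = min(max(n_train, 1), len(group) - 1)  # both splits non-empty
        for rank, idx in enumerate(order):
            split[group[idx]] = "train" if rank < n_train else "test"

    from . import gdps as _gdps

    gdps_values = {
        pair: _gdps.score_pair(ctx, *pair) for pair in positives + negatives
    }
    labeled = LabeledEdgeSet(
        positives=positives,
        negatives=negatives,
        pair_type=pair_type,
        split=split,
        seed=seed,
        gdps=gdps_values,
    )
    return labeled, g_prime


def uniform_gd_non_edges(g: HetGraph, count: int, seed: int) -> set[GdEdge]:
    """Uniformly sampled gene-disease non-edges (baseline for comparisons)."""
    rng = np.random.default_rng(seed)
    genes = sorted(g.gene_nodes)
    diseases = sorted(g.disease_nodes)
    non_edges = [
        (gene, d) for gene in genes for d in diseases if not g.adjacent(gene, d)
    ]
    if count > len(non_edges):
        raise SamplingError("not enough gene-disease non-edges")
    idx = rng.choice(len(non_edges), size=count, replace=False)
    return {non_edges[i] for i in idx}
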