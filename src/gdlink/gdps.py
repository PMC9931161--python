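"""Gene-Disease Prioritization Score (GDPS).

GDPS of a candidate gene *g* for a disease *d* is the mean co-expression
similarity between *g* and the genes already known to associate with *d*
in the train-time graph G' (test edges removed). Intuitively it asks: does
this gene co-express with the disease's known gene set? High GDPS means
the gene behaves transcriptionally like a disease gene even if the graph
contains no path connecting them.

Gene-gene pairs carry no disease context; their score is defined as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hetgraph import HetGraph
from .tables_io import CoexpressionMatrix

logger = logging.getLogger(__name__)


class GdpsError(ValueError):
    """Score requested for an unknown or unscoreable disease/pair."""


class UnscoreableDiseaseError(GdpsError):
    """The disease has no known gene present in the similarity matrix.

    Raised instead of returning 0 so callers can distinguish "no basis
    for a score" from a legitimately zero mean similarity.
    """


@dataclass
class GdpsContext:
    """Everything needed to score: the reduced graph G' and the matrix Z.

    ``graph`` must be the train-time graph (held-out positive edges already
    removed), otherwise scores leak test information. ``missing_policy``
    currently supports only ``"zero"``: a candidate gene absent from Z
    scores 0, the same neutral sentinel used for gene-gene pairs.
    """

    graph: HetGraph
    matrix: CoexpressionMatrix
    missing_policy: str = "zero"

    def __post_init__(self) -> None:
        if self.missing_policy != "zero":
            raise GdpsError(f"unsupported missing_policy {self.missing_policy!r}")
        self._known_cache: dict[str, list[int]] = {}
        self._profile_cache: dict[str, np.ndarray] = {}
        self._warned_missing: set[str] = set()

    def known_gene_positions(self, disease: str) -> list[int]:
        """Matrix column positions of the disease's known genes in G'.

        Known genes absent from Z are skipped (not imputed as 0): the mean
        is taken over similarities that actually exist.
        """
        if disease not in self._known_cache:
            if disease not in self.graph.disease_nodes:
                raise GdpsError(f"unknown disease {disease!r}")
            known = self.graph.genes_of(disease)
            self._known_cache[disease] = sorted(
                self.matrix.position(g) for g in known if g in self.matrix
            )
        return self._known_cache[disease]

    def profile(self, disease: str) -> np.ndarray:
        """GDPS of every gene in Z against ``disease``, as a vector.

        Entry ``i`` is the mean similarity of gene ``gene_index[i]`` to
        the disease's known genes — one column-subset row-mean of Z.
        """
        if disease not in self._profile_cache:
            pos = self.known_gene_positions(disease)
            if not pos:
                raise UnscoreableDiseaseError(
                    f"disease {disease!r} has no known gene present in the matrix"
                )
            self._profile_cache[disease] = self.matrix.values[:, pos].mean(axis=1)
        return self._profile_cache[disease]


def score(ctx: GdpsContext, gene: str, disease: str) -> float:
    """Mean similarity of ``gene`` to the known genes of ``disease`` in G'.

    Returns 0 when the gene is absent from the similarity matrix (logged
    once per gene). If the gene is itself adjacent to the disease its own
    unit self-similarity participates in the mean, as-is.
    """
    prof = ctx.profile(disease)
    if gene not in ctx.matrix:
        if gene not in ctx._warned_missing:
            logger.warning("gene %s absent from co-expression matrix; GDPS = 0", gene)
            ctx._warned_missing.add(gene)
        return 0.0
    return float(prof[ctx.matrix.position(gene)])


def score_pair(ctx: GdpsContext, a: str, b: str) -> float:
    """GDPS for an arbitrary node pair; 0 for gene-gene pairs."""
    a_is_d = ctx.graph.is_disease(a)
    b_is_d = ctx.graph.is_disease(b)
    if a_is_d and b_is_d:
        raise GdpsError(f"disease-disease pair ({a}, {b}) is unsupported")
    if not a_is_d and not b_is_d:
        return 0.0
    gene, disease = (b, a) if a_is_d else (a, b)
    return score(ctx, gene, disease)


def score_all_candidates(ctx: GdpsContext, disease: str) -> dict[str, float]:
    """GDPS for every gene of Z not already adjacent to ``disease`` in G'."""
    prof = ctx.profile(disease)
    known = ctx.graph.genes_of(disease)
    return {
        g: float(prof[i])
        for i, g in enumerate(ctx.matrix.gene_index)
        if g not in known
    }


def export_scores(scores: dict[str, float], path) -> None:
    """Write per-disease candidate scores as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("gene\tgdps\n")
        for g in sorted(scores):
            fh.write(f"{g}\t{scores[g]:.10g}\n")
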