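"""End-to-end orchestration of the link-prediction pipeline.

Glue only — each stage lives in its own module. ``run_pipeline`` takes
the three (possibly synthetic) inputs through filtering, graph building,
labeled-set generation, embedding, classification and the novel-gene
evaluation layer, and returns every intermediate a caller might want.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import discovery, edge_sampling, embedding, hetgraph, link_classifier
from .discovery import ClusterModel, HoldoutSpec, OverlapReport
from .edge_sampling import LabeledEdgeSet
from .embedding import EmbeddingConfig, EmbeddingTable
from .gdps import GdpsContext
from .hetgraph import HetGraph
from .link_classifier import EvalReport
from .tables_io import (
    AssociationRecord,
    CoexpressionMatrix,
    TissueRecord,
    filter_associations,
    filter_tissue,
)


@dataclass
class PipelineResult:
    graph: HetGraph
    g_prime: HetGraph
    labeled: LabeledEdgeSet
    table: EmbeddingTable
    ctx: GdpsContext
    model: object
    model_no_gdps: object
    report: EvalReport
    report_no_gdps: EvalReport
    cv_with: tuple[float, float]
    cv_without: tuple[float, float]
    holdout: dict[str, set[str]] = field(default_factory=dict)
    overlap_reports: dict[str, dict[int, OverlapReport]] = field(default_factory=dict)
    ratio: dict[int, float] = field(default_factory=dict)
    best_f: int | None = None
    mean_probs: dict[str, float] = field(default_factory=dict)
    clusters: ClusterModel | None = None
    cluster_tests: dict | None = None


def build_graph(
    associations: list[AssociationRecord],
    tissue_records: list[TissueRecord],
) -> HetGraph:
    """Filter both tables and integrate the two graph layers."""
    assoc = filter_associations(associations)
    pairs = filter_tissue(tissue_records)
    gd = hetgraph.build_gd_graph(assoc)
    gg = hetgraph.build_gg_graph(pairs)
    return hetgraph.integrate(gd, gg)


def run_pipeline(
    associations: list[AssociationRecord],
    tissue_records: list[TissueRecord],
    matrix: CoexpressionMatrix,
    seed: int,
    fraction: float = 0.2,
    train_frac: float = 0.7,
    emb_cfg: EmbeddingConfig | None = None,
    cv_folds: int = 10,
    holdout_year: int | None = None,
    cluster_k_range: tuple[int, int] = (2, 9),
) -> PipelineResult:
    """Run the whole pipeline; ``holdout_year`` enables the discovery layer."""
    graph = build_graph(associations, tissue_records)
    ctx = GdpsContext(graph=graph, matrix=matrix)
    labeled, g_prime = edge_sampling.make_labeled_set(
        graph, fraction, train_frac, ctx, seed
    )
    ctx = replace(ctx, graph=g_prime)

    emb_cfg = emb_cfg or EmbeddingConfig()
    emb_cfg = replace(emb_cfg, seed=seed)
    table = embedding.embed_graph(g_prime, emb_cfg)

    results = {}
    for use_gdps in (True, False):
        train_feats = link_classifier.build_features(
            labeled, table, ctx, use_gdps=use_gdps, split="train"
        )
        test_feats = link_classifier.build_features(
            labeled, table, ctx, use_gdps=use_gdps, split="test"
        )
        cv = link_classifier.cross_validate(train_feats, cv_folds, seed)
        model = link_classifier.train(train_feats, seed)
        report = link_classifier.evaluate(model, test_feats)
        results[use_gdps] = (model, report, cv)

    model, report, cv_with = results[True]
    model_ng, report_ng, cv_without = results[False]

    result = PipelineResult(
        graph=graph,
        g_prime=g_prime,
        labeled=labeled,
        table=table,
        ctx=ctx,
        model=model,
        model_no_gdps=model_ng,
        report=report,
        report_no_gdps=report_ng,
        cv_with=cv_with,
        cv_without=cv_without,
    )

    if holdout_year is not None:
        spec = HoldoutSpec(year=holdout_year)
        holdout = discovery.build_holdout(associations, g_prime, spec)
        ranked_by_disease = {}
        for d, i_d in sorted(holdout.items()):
            ranked = discovery.rank_candidates(model, g_prime, table, ctx, d)
            if not ranked:
                continue
            ranked_by_disease[d] = ranked
            result.overlap_reports[d] = discovery.overlap_grid(ranked, i_d, d)
        result.holdout = holdout
        if result.overlap_reports:
            result.ratio, result.best_f = discovery.ratio_curve(
                result.overlap_reports
            )
        result.mean_probs = discovery.mean_link_probability(ranked_by_disease)
        if len(result.mean_probs) >= cluster_k_range[0]:
            overlaps_at_best = {
                d: result.overlap_reports[d][result.best_f].overlap
                for d in result.overlap_reports
                if result.best_f in result.overlap_reports[d]
            }
            result.clusters = discovery.cluster_success(
                result.mean_probs, cluster_k_range, overlaps=overlaps_at_best
            )
            by_cluster: dict[int, list[float]] = {}
            for d, c in result.clusters.assignment.items():
                by_cluster.setdefault(c, []).append(result.mean_probs[d])
            try:
                result.cluster_tests = discovery.compare_clusters(by_cluster)
            except discovery.DiscoveryError:
                result.cluster_tests = None
    return result
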