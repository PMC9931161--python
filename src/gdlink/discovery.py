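"""Novel-gene evaluation: temporal holdout, Overlap/Ratio, success clusters.

A temporal holdout treats associations first reported in a cutoff year as
"future" knowledge: the model, trained on the reduced graph G', must
rediscover them among all candidate genes. Per disease d with held-out
gene set I_d, the ranked candidate predictions give

    Overlap(f%) = |P_f% ∩ I_d| / |I_d|

where P_f% is the top f% of candidates predicted to form a link. Across
diseases, Ratio(f) = (#diseases with Overlap = 1) / f trades recovery
against wet-lab candidate volume; its argmax selects the cutoff.

In deployment I_d is unknown, so per-disease mean prediction probabilities
are clustered with an exact (dynamic-programming) univariate k-means and
cluster membership serves as a proxy for expected Overlap; Kruskal-Wallis
tests confirm the clusters differ in their probability distributions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .embedding import EmbeddingTable
from .gdps import GdpsContext
from .hetgraph import HetGraph
from .link_classifier import feature_pair
from .tables_io import AssociationRecord, DISEASE_OR_SYNDROME

logger = logging.getLogger(__name__)


class DiscoveryError(ValueError):
    pass


@dataclass(frozen=True)
class HoldoutSpec:
    """Filters defining the temporal holdout set.

    ``year``: associations first reported in this year are the holdout.
    ``min_new_genes``: diseases with fewer new genes are dropped (must be
    >= 2 so each surviving disease offers a non-trivial recovery task).
    ``dsi_rule``/``dpi_rule``: keep only genes with above-average DSI and
    below-average DPI — i.e. specific, non-pleiotropic genes whose
    rediscovery is not trivially implied by high connectivity.
    """

    year: int
    min_new_genes: int = 2
    dsi_rule: bool = True
    dpi_rule: bool = True

    def __post_init__(self) -> None:
        if self.min_new_genes < 2:
            raise DiscoveryError("min_new_genes must be >= 2")


@dataclass
class OverlapReport:
    disease: str
    f_percent: int
    candidates_ranked: list[tuple[str, float]]
    p_f: set[str]
    i_d: set[str]
    overlap: float


@dataclass
class ClusterModel:
    k: int
    centers: list[float]
    assignment: dict[str, int]  # disease -> cluster index (by ascending center)
    overlap_band: dict[int, str] = field(default_factory=dict)  # "low"|"mid"|"high"
    bic: list[float] = field(default_factory=list)


def build_holdout(
    associations: Iterable[AssociationRecord],
    g_prime: HetGraph,
    spec: HoldoutSpec,
) -> dict[str, set[str]]:
    """Construct per-disease held-out gene sets I_d from the raw table.

    Filter cascade, in order: (1) rows of the holdout year with disease
    type 'disease' and semantic type 'Disease or Syndrome'; (2) drop
    diseases with fewer than ``min_new_genes`` new genes; (3) drop pairs
    still present as edges of G'; (4) keep genes with DSI above the mean
    DSI and DPI below the mean DPI, means taken over distinct genes of
    the full table. Diseases left empty are dropped with a warning.
    """
    associations = list(associations)

    by_gene_dsi: dict[str, float] = {}
    by_gene_dpi: dict[str, float] = {}
    for r in associations:
        if r.dsi is not None:
            by_gene_dsi.setdefault(r.gene_symbol, r.dsi)
        if r.dpi is not None:
            by_gene_dpi.setdefault(r.gene_symbol, r.dpi)
    mean_dsi = float(np.mean(list(by_gene_dsi.values()))) if by_gene_dsi else 0.0
    mean_dpi = float(np.mean(list(by_gene_dpi.values()))) if by_gene_dpi else 1.0

    new_rows = [
        r
        for r in associations
        if r.year_initial == spec.year
        and r.disease_type == "disease"
        and r.semantic_type.strip().lower() == DISEASE_OR_SYNDROME.lower()
    ]
    genes_per_disease: dict[str, set[str]] = {}
    for r in new_rows:
        genes_per_disease.setdefault(r.disease_id, set()).add(r.gene_symbol)
    eligible = {
        d for d, gs in genes_per_disease.items() if len(gs) >= spec.min_new_genes
    }

    holdout: dict[str, set[str]] = {}
    for r in new_rows:
        d = r.disease_id
        if d not in eligible or d not in g_prime.disease_nodes:
            continue
        if g_prime.has_gd_edge(r.gene_symbol, d):
            continue
        if spec.dsi_rule:
            dsi = by_gene_dsi.get(r.gene_symbol)
            if dsi is None or dsi <= mean_dsi:
                continue
        if spec.dpi_rule:
            dpi = by_gene_dpi.get(r.gene_symbol)
            if dpi is None or dpi >= mean_dpi:
                continue
        holdout.setdefault(d, set()).add(r.gene_symbol)

    if not holdout:
        logger.warning("temporal holdout is empty under year=%d", spec.year)
    return holdout


def rank_candidates(
    model,
    g_prime: HetGraph,
    tbl: EmbeddingTable,
    ctx: GdpsContext,
    disease: str,
    use_gdps: bool = True,
) -> list[tuple[str, float]]:
    """Rank every non-associated gene of G' for one disease.

    All genes of G' without an association edge to the disease are
    featurized and scored; only genes classified into the link-formation
    class (probability >= 0.5) are returned, sorted by descending
    probability with lexicographic tie-breaks.
    """
    if disease not in g_prime.disease_nodes:
        raise DiscoveryError(f"unknown disease {disease!r}")
    known = g_prime.genes_of(disease)
    candidates = sorted(g_prime.gene_nodes - known)
    if not candidates:
        return []
    X = np.vstack(
        [feature_pair(tbl, ctx, gene, disease, use_gdps) for gene in candidates]
    )
    prob = model.predict_proba(X)[:, 1]
    kept = [(g, float(p)) for g, p in zip(candidates, prob) if p >= 0.5]
    kept.sort(key=lambda gp: (-gp[1], gp[0]))
    return kept


def overlap(
    ranked: Sequence[tuple[str, float]],
    i_d: set[str],
    f_percent: int,
    disease: str = "",
) -> OverlapReport:
    """Overlap(f%) = |P_f% ∩ I_d| / |I_d| with a ceil top-f% cutoff."""
    if not i_d:
        raise DiscoveryError("held-out gene set I_d is empty")
    if not (1 <= f_percent <= 100):
        raise DiscoveryError("f_percent must lie in [1, 100]")
    cutoff = math.ceil(f_percent / 100.0 * len(ranked))
    p_f = {g for g, _ in ranked[:cutoff]}
    return OverlapReport(
        disease=disease,
        f_percent=f_percent,
        candidates_ranked=list(ranked),
        p_f=p_f,
        i_d=set(i_d),
        overlap=len(p_f & i_d) / len(i_d),
    )


DEFAULT_F_GRID = tuple(range(10, 101, 10))


def overlap_grid(
    ranked: Sequence[tuple[str, float]],
    i_d: set[str],
    disease: str = "",
    grid: Sequence[int] = DEFAULT_F_GRID,
) -> dict[int, OverlapReport]:
    return {f: overlap(ranked, i_d, f, disease) for f in grid}


def ratio_curve(
    reports: Mapping[str, Mapping[int, OverlapReport]],
) -> tuple[dict[int, float], int]:
    """Ratio(f) = #{diseases with Overlap(f) = 1} / f, plus its argmax.

    The denominator is the percentage as a number (30, not 0.3). Ties on
    the maximum resolve to the smallest f (fewer candidate genes to test).
    """
    if not reports:
        raise DiscoveryError("no overlap reports")
    grid = sorted({f for per_d in reports.values() for f in per_d})
    curve = {
        f: sum(1 for per_d in reports.values() if f in per_d and per_d[f].overlap == 1.0)
        / f
        for f in grid
    }
    best_f = max(grid, key=lambda f: (curve[f], -f))
    return curve, best_f


def mean_link_probability(
    ranked_by_disease: Mapping[str, Sequence[tuple[str, float]]],
) -> dict[str, float]:
    """Per-disease mean probability over link-formation-class candidates."""
    out = {}
    for d, ranked in ranked_by_disease.items():
        if ranked:
            out[d] = float(np.mean([p for _, p in ranked]))
    return out


# -- exact univariate k-means --------------------------------------------


def _kmeans_1d_dp(x: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Globally optimal k-means on sorted 1-D data by dynamic programming.

    Returns (labels over the sorted order, total within-cluster sum of
    squares). O(k n^2) with prefix sums; exact, unlike Lloyd iterations.
    """
    n = len(x)
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:
        # WCSS of x[i..j] inclusive
        s = pref[j + 1] - pref[i]
        s2 = pref2[j + 1] - pref2[i]
        m = j - i + 1
        return max(0.0, s2 - s * s / m)

    D = np.full((k + 1, n + 1), np.inf)
    B = np.zeros((k + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            best, arg = np.inf, kk - 1
            for i in range(kk - 1, j):
                c = D[kk - 1, i] + cost(i, j - 1)
                if c < best:
                    best, arg = c, i
            D[kk, j] = best
            B[kk, j] = arg
    labels = np.zeros(n, dtype=int)
    j = n
    for kk in range(k, 0, -1):
        i = B[kk, j]
        labels[i:j] = kk - 1
        j = i
    return labels, float(D[k, n])


def _bic_1d(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC of the Gaussian-mixture interpretation of a 1-D clustering.

    Cluster variances use the unbiased estimator; singleton or
    zero-variance clusters fall back to the overall sample variance so
    that shattering the data into tiny clusters cannot inflate the
    likelihood without bound.
    """
    n = len(x)
    overall_var = max(float(np.var(x)), 1e-12)
    loglik = 0.0
    for c in range(k):
        xi = x[labels == c]
        m = len(xi)
        if m == 0:
            continue
        mu = xi.mean()
        if m >= 2:
            var = float(np.sum((xi - mu) ** 2)) / (m - 1)
        else:
            var = overall_var
        if var <= 0:
            var = overall_var
        loglik += m * math.log(m / n)
        loglik += -0.5 * m * math.log(2 * math.pi * var) - 0.5 * np.sum(
            (xi - mu) ** 2
        ) / var
    n_params = 3 * k - 1  # k means, k variances, k-1 free weights
    return -2.0 * loglik + n_params * math.log(n)


def cluster_success(
    mean_probs: Mapping[str, float],
    k_range: tuple[int, int] = (2, 9),
    overlaps: Mapping[str, float] | None = None,
) -> ClusterModel:
    """Cluster per-disease mean probabilities into success levels.

    Exact DP k-means per candidate k; k chosen by minimum BIC over
    ``k_range`` (capped at the number of distinct values). Clusters are
    indexed by ascending center. Bands: with known overlaps, each cluster
    takes the majority band of its members ([0, 0.5] -> low, (0.5, 1) ->
    mid, {1} -> high); without, bands are assigned by center rank.
    """
    k_min, k_max = k_range
    diseases = sorted(mean_probs)
    if len(diseases) < k_min:
        raise DiscoveryError(
            f"{len(diseases)} diseases < minimum cluster count {k_min}"
        )
    values = np.array([mean_probs[d] for d in diseases])
    order = np.argsort(values, kind="stable")
    x = values[order]
    n_distinct = len(np.unique(x))
    if n_distinct == 1:
        # constant input: a single effective cluster; k collapses below
        # the searched range rather than reporting an arbitrary split
        return ClusterModel(
            k=1,
            centers=[float(x[0])],
            assignment={d: 0 for d in diseases},
            overlap_band={0: "low"},
            bic=[],
        )
    k_hi = min(k_max, len(diseases), max(k_min, n_distinct))

    best = None
    bics = []
    for k in range(k_min, k_hi + 1):
        if k > n_distinct and k > k_min:
            break
        labels, _ = _kmeans_1d_dp(x, k)
        bic = _bic_1d(x, labels, k)
        bics.append(bic)
        if best is None or bic < best[0]:
            best = (bic, k, labels)
    assert best is not None
    _, k, labels = best

    assignment = {diseases[order[i]]: int(labels[i]) for i in range(len(diseases))}
    centers = [float(x[labels == c].mean()) for c in range(k)]

    bands: dict[int, str] = {}
    if overlaps:
        for c in range(k):
            members = [d for d, cc in assignment.items() if cc == c and d in overlaps]
            if members:
                votes = [_band_of(overlaps[d]) for d in members]
                bands[c] = max(set(votes), key=votes.count)
            else:
                bands[c] = _rank_band(c, k)
    else:
        for c in range(k):
            bands[c] = _rank_band(c, k)

    return ClusterModel(
        k=k, centers=centers, assignment=assignment, overlap_band=bands, bic=bics
    )


def _band_of(overlap_value: float) -> str:
    if overlap_value == 1.0:
        return "high"
    if overlap_value > 0.5:
        return "mid"
    return "low"


def _rank_band(cluster: int, k: int) -> str:
    if k == 1:
        return "low"
    if cluster == 0:
        return "low"
    if cluster == k - 1:
        return "high"
    return "mid"


def compare_clusters(
    probs_by_cluster: Mapping[int, Sequence[float]],
) -> dict:
    """Kruskal-Wallis omnibus plus all pairwise tests across clusters.

    No multiplicity correction is applied to the pairwise p-values; the
    report flags this so consumers can correct downstream if needed.
    """
    groups = {c: np.asarray(v, dtype=float) for c, v in probs_by_cluster.items()}
    usable = {c: v for c, v in groups.items() if len(v) >= 2}
    skipped = sorted(set(groups) - set(usable))
    for c in skipped:
        warnings.warn(f"cluster {c} has < 2 observations; excluded from tests")
    if len(usable) < 2:
        raise DiscoveryError("need at least two clusters with >= 2 observations")
    keys = sorted(usable)
    H, p = stats.kruskal(*[usable[c] for c in keys])
    pairwise = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            h2, p2 = stats.kruskal(usable[a], usable[b])
            pairwise[f"{a}-{b}"] = {"H": float(h2), "p": float(p2)}
    return {
        "omnibus": {"H": float(H), "p": float(p)},
        "pairwise": pairwise,
        "skipped_clusters": skipped,
        "multiplicity_correction": "none",
    }
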