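"""Synthetic generators for the three input tables.

The simulator plants a module structure that makes co-expression
informative about held-out associations, which is the property the whole
pipeline exists to exploit:

* genes are partitioned into co-expression modules; same-module pairs get
  a high mean similarity, cross-module pairs a low one, plus Gaussian
  noise (symmetrized, clipped to [-1, 1], unit diagonal);
* each disease draws its gene set predominantly from one "home" module,
  so a disease's unseen genes co-express with its known genes;
* tissues sample genes from a single module and most gene-tissue calls
  are emitted as High/Approved in two cell types, so the tissue filter
  keeps them and the gene-gene layer mirrors module structure;
* a fraction of each disease's associations is stamped with a future
  discovery year (the temporal holdout), and those genes are biased
  toward high DSI / low DPI so a known share survives the holdout filter.

The matrix is not forced positive semidefinite: the score reads entries
element-wise, so only the entry distribution matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .hetgraph import HetGraph
from .tables_io import (
    AssociationRecord,
    CoexpressionMatrix,
    DISEASE_OR_SYNDROME,
    TissueRecord,
    write_associations,
    write_coexpression,
    write_tissue,
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic tables.

    Defaults describe a desk-scale corpus: 500 genes in 5 co-expression
    modules, 40 diseases drawing 10-20 genes each mostly from one module,
    within/between-module mean similarity 0.7 / 0.05 with noise SD 0.1
    (strong but realistic module contrast for curated co-expression), 10
    tissues, and 30% of each disease's genes stamped with the future
    discovery year.
    """

    n_genes: int = 500
    n_diseases: int = 40
    n_modules: int = 5
    n_tissues: int = 10
    genes_per_disease: tuple[int, int] = (10, 20)
    home_module_frac: float = 0.9
    within_module_corr: float = 0.7
    between_module_corr: float = 0.05
    corr_noise_sd: float = 0.1
    holdout_year_fraction: float = 0.3
    future_year: int = 2020
    past_years: tuple[int, int] = (1990, 2019)
    future_pass_frac: float = 0.7
    two_celltype_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_disease[1] > self.n_genes:
            raise SimulationError("genes_per_disease exceeds n_genes")
        if not (self.between_module_corr < self.within_module_corr):
            raise SimulationError("within-module similarity must exceed between")
        for v in (self.within_module_corr, self.between_module_corr):
            if not (-1.0 < v < 1.0):
                raise SimulationError("correlations must lie in (-1, 1)")
        if self.n_modules < 1 or self.n_modules > self.n_genes:
            raise SimulationError("invalid module count")


@dataclass
class SimTruth:
    """Ground truth of the simulation, for evaluation only."""

    module_of: dict[str, int]
    future_edges: list[tuple[str, str]]  # (gene, disease) stamped future_year
    home_module: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "module_of": self.module_of,
                    "future_edges": [list(e) for e in self.future_edges],
                    "home_module": self.home_module,
                },
                fh,
                indent=2,
            )


def simulate(
    cfg: SimConfig,
) -> tuple[list[AssociationRecord], list[TissueRecord], CoexpressionMatrix, SimTruth]:
    """Generate the three tables plus ground truth, deterministically."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    diseases = [f"C{i:04d}" for i in range(cfg.n_diseases)]
    module_of = {g: i % cfg.n_modules for i, g in enumerate(genes)}

    matrix = _simulate_matrix(cfg, rng, genes, module_of)

    # per-gene DSI/DPI; refined below for future-edge genes
    dsi = {g: float(rng.uniform(0.25, 1.0)) for g in genes}
    dpi = {g: float(rng.uniform(0.0, 1.0)) for g in genes}

    associations: list[AssociationRecord] = []
    future_edges: list[tuple[str, str]] = []
    home_module: dict[str, int] = {}
    future_genes: set[str] = set()
    for d_idx, d in enumerate(diseases):
        home = d_idx % cfg.n_modules
        home_module[d] = home
        size = int(rng.integers(cfg.genes_per_disease[0], cfg.genes_per_disease[1] + 1))
        pool_home = [g for g in genes if module_of[g] == home]
        n_home = min(len(pool_home), int(round(cfg.home_module_frac * size)))
        chosen = list(rng.choice(pool_home, size=n_home, replace=False))
        others = [g for g in genes if g not in set(chosen)]
        n_other = size - n_home
        if n_other > 0:
            chosen += list(rng.choice(others, size=n_other, replace=False))
        n_future = int(round(cfg.holdout_year_fraction * len(chosen)))
        future_idx = set(rng.choice(len(chosen), size=n_future, replace=False))
        for i, g in enumerate(chosen):
            is_future = i in future_idx
            year = (
                cfg.future_year
                if is_future
                else int(rng.integers(cfg.past_years[0], cfg.past_years[1] + 1))
            )
            if is_future:
                future_edges.append((g, d))
                future_genes.add(g)
            associations.append(
                AssociationRecord(
                    gene_symbol=g,
                    disease_id=d,
                    disease_name=f"disease {d}",
                    disease_type="disease",
                    semantic_type=DISEASE_OR_SYNDROME,
                    dsi=dsi[g],
                    dpi=dpi[g],
                    year_initial=year,
                )
            )

    # bias future-edge genes so ~future_pass_frac of them survive the
    # above-mean-DSI / below-mean-DPI holdout filter
    new_dsi = dict(dsi)
    new_dpi = dict(dpi)
    for g in sorted(future_genes):
        if rng.random() < cfg.future_pass_frac:
            new_dsi[g] = float(rng.uniform(0.85, 1.0))
            new_dpi[g] = float(rng.uniform(0.0, 0.15))
        else:
            new_dsi[g] = float(rng.uniform(0.25, 0.4))
            new_dpi[g] = float(rng.uniform(0.85, 1.0))
    associations = [
        AssociationRecord(
            gene_symbol=r.gene_symbol,
            disease_id=r.disease_id,
            disease_name=r.disease_name,
            disease_type=r.disease_type,
            semantic_type=r.semantic_type,
            dsi=new_dsi[r.gene_symbol],
            dpi=new_dpi[r.gene_symbol],
            year_initial=r.year_initial,
        )
        for r in associations
    ]

    tissue_records = _simulate_tissue(cfg, rng, genes, module_of)
    truth = SimTruth(
        module_of=module_of, future_edges=future_edges, home_module=home_module
    )
    return associations, tissue_records, matrix, truth


def _simulate_matrix(
    cfg: SimConfig,
    rng: np.random.Generator,
    genes: list[str],
    module_of: dict[str, int],
) -> CoexpressionMatrix:
    n = len(genes)
    mods = np.array([module_of[g] for g in genes])
    base = np.where(
        mods[:, None] == mods[None, :],
        cfg.within_module_corr,
        cfg.between_module_corr,
    )
    noise = rng.normal(0.0, cfg.corr_noise_sd, size=(n, n))
    z = base + (noise + noise.T) / 2.0
    z = np.clip(z, -1.0, 1.0)
    np.fill_diagonal(z, 1.0)
    return CoexpressionMatrix(gene_index=list(genes), values=z)


def _simulate_tissue(
    cfg: SimConfig,
    rng: np.random.Generator,
    genes: list[str],
    module_of: dict[str, int],
) -> list[TissueRecord]:
    records: list[TissueRecord] = []
    by_module: dict[int, list[str]] = {}
    for g in genes:
        by_module.setdefault(module_of[g], []).append(g)
    for t_idx in range(cfg.n_tissues):
        tissue = f"tissue_{t_idx:02d}"
        module = t_idx % cfg.n_modules
        pool = by_module[module]
        size = max(2, int(round(len(pool) * 0.4)))
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        for g in members:
            if rng.random() < cfg.two_celltype_frac:
                cell_types = ["ct_a", "ct_b"]
                level, rel = "High", "Approved"
            else:
                cell_types = ["ct_a"]
                # single-cell-type or low-confidence rows: filtered out later
                level, rel = ("High", "Approved") if rng.random() < 0.5 else (
                    "Medium",
                    "Uncertain",
                )
            for ct in cell_types:
                records.append(
                    TissueRecord(
                        gene_id=g,
                        tissue=tissue,
                        cell_type=ct,
                        expression_level=level,
                        reliability=rel,
                    )
                )
    return records


def write_simulation(
    cfg: SimConfig, outdir: str | Path
) -> dict[str, Path]:
    """Run :func:`simulate` and write the tables in the dialects the
    readers expect, plus the truth JSON. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    associations, tissue, matrix, truth = simulate(cfg)
    paths = {
        "associations": outdir / "associations.tsv",
        "tissue": outdir / "tissue.tsv",
        "coexpression": outdir / "coexpression.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.json",
    }
    write_associations(associations, paths["associations"])
    write_tissue(tissue, paths["tissue"])
    write_coexpression(matrix, paths["coexpression"])
    truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2)
    return paths


def fig2_fixture() -> tuple[HetGraph, CoexpressionMatrix]:
    """Tiny worked-example fixture for the prioritization score.

    Disease ``d`` is associated with genes ``g2`` and ``g3``; the
    similarity of candidate ``g1`` to them is 0.1 and 0.4, so its score
    for ``d`` is (0.1 + 0.4) / 2 = 0.25. Deterministic, no seed.
    """
    genes = ["g1", "g2", "g3", "g4"]
    z = np.array(
        [
            [1.0, 0.1, 0.4, 0.2],
            [0.1, 1.0, 0.3, 0.5],
            [0.4, 0.3, 1.0, 0.6],
            [0.2, 0.5, 0.6, 1.0],
        ]
    )
    matrix = CoexpressionMatrix(gene_index=genes, values=z)
    graph = HetGraph(
        disease_nodes={"d"},
        gene_nodes=set(genes),
        gd_edges={("g2", "d"), ("g3", "d")},
    )
    return graph, matrix
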