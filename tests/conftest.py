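import numpy as np
import pytest

from gdlink.gdps import GdpsContext
from gdlink.hetgraph import HetGraph
from gdlink.pipeline import run_pipeline
from gdlink.synthetic_data import SimConfig, fig2_fixture, simulate
from gdlink.tables_io import CoexpressionMatrix


@pytest.fixture
def fig2():
    """Worked-example fixture: disease d with known genes g2, g3."""
    graph, matrix = fig2_fixture()
    return GdpsContext(graph=graph, matrix=matrix)


def random_coexpression(n_genes: int, seed: int) -> CoexpressionMatrix:
    """A random valid similarity matrix (symmetric, unit diagonal)."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(-1, 1, size=(n_genes, n_genes))
    z = (z + z.T) / 2
    np.fill_diagonal(z, 1.0)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    return CoexpressionMatrix(gene_index=genes, values=z)


def random_gd_graph(
    n_genes: int, n_diseases: int, degree: int, seed: int
) -> HetGraph:
    """A gene-disease graph with `degree` random genes per disease."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    diseases = [f"D{i:02d}" for i in range(n_diseases)]
    edges = set()
    for d in diseases:
        for i in rng.choice(n_genes, size=degree, replace=False):
            edges.add((genes[i], d))
    return HetGraph(
        disease_nodes=set(diseases), gene_nodes=set(genes), gd_edges=edges
    )


@pytest.fixture
def gdps_fixture_50():
    """50-gene random matrix + graph, for oracle cross-checks."""
    matrix = random_coexpression(50, seed=7)
    graph = random_gd_graph(50, 8, degree=5, seed=8)
    return GdpsContext(graph=graph, matrix=matrix)


#: generator defaults — the study conditions for end-to-end checks
DEFAULT_SIM_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def pipeline_runs():
    """Full pipeline on the generator defaults for 10 seeds (shared)."""
    runs = []
    for seed in DEFAULT_SIM_SEEDS:
        cfg = SimConfig(seed=seed)
        associations, tissue, matrix, truth = simulate(cfg)
        res = run_pipeline(
            associations,
            tissue,
            matrix,
            seed=seed,
            holdout_year=cfg.future_year,
        )
        runs.append((cfg, truth, res))
    return runs
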