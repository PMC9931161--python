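# gdlink

Gene–disease link prediction on a heterogeneous graph, with a
co-expression-based gene prioritization score.

## The problem

Predicting which genes are involved in a disease from graph structure
alone misses biology that is not yet in the graph: two genes can share a
pathway without sharing an edge, because the supporting experiments have
not been done. `gdlink` is for computational biologists who want to rank
candidate disease genes by combining two complementary signals:

1. **network structure** — an undirected heterogeneous graph `G` with
   gene and disease nodes, gene–disease association edges (from a
   DisGeNET-style table) and tissue-derived gene–gene edges (genes
   co-reported in a tissue, from a Human Protein Atlas-style table,
   connected as one clique per tissue); and
2. **gene co-expression** — a Gene–Disease Prioritization Score (GDPS).
   For a candidate gene *g* and disease *d* with known gene set
   N(d) = {g₁, …, g_k} in the training graph G′,

   GDPS(g, d) = (1/k) · Σᵢ Z[g, gᵢ]

   where Z is a gene×gene Pearson co-expression similarity matrix
   (ARCHS4-style). Gene–gene pairs are assigned GDPS = 0.

Node embeddings of G′ are learned with second-order biased random walks
plus skip-gram; a labeled pair (u, v) is represented as u + v with GDPS
appended, and an L2 logistic regression classifies pairs into *link
formation* vs *no link formation*. Negative training pairs are half
uniform gene–gene non-edges and half gene–disease non-edges chosen with
the **lowest** GDPS — pairs least likely to be unreported true
associations, which reduces label noise.

A temporal-holdout layer measures novel-gene discovery: associations
first reported in a cutoff year are hidden, every candidate gene is
ranked per disease, and recovery is summarized by

- **Overlap(f%)** = |P_f% ∩ I_d| / |I_d|, the fraction of a disease's
  held-out genes found in the top f% of its ranked predictions, and
- **Ratio(f)** = #{d : Overlap(d) = 1} / f, maximized to pick the
  cutoff f.

Per-disease mean prediction probabilities are then clustered with an
exact (dynamic-programming) univariate k-means, BIC-selected k in 2–9,
so that in deployment — where I_d is unknown — a disease's cluster
estimates its expected Overlap band; Kruskal–Wallis tests check that the
clusters genuinely differ.

## Worked example

The package ships a synthetic-data generator that plants co-expression
modules, so the whole pipeline runs offline:

```python
from gdlink import SimConfig, simulate, run_pipeline

cfg = SimConfig(seed=1)                      # 500 genes, 40 diseases, 5 modules
associations, tissue, matrix, truth = simulate(cfg)
res = run_pipeline(associations, tissue, matrix, seed=1,
                   holdout_year=cfg.future_year)
```

which prints (via the summary statements in `examples`-style use):

```
graph: 40 diseases, 421 genes, 584 gene-disease edges, 3939 gene-gene edges
labeled set: 120 positives, 120 negatives
test metrics (with GDPS):    micro-F1 0.958  precision 1.000  recall 0.917  AUC 0.977
test metrics (without GDPS): micro-F1 0.417  AUC 0.351
10-fold CV micro-F1: 0.947 +/- 0.049 (with) vs 0.439 +/- 0.102 (without)
temporal holdout: 23 diseases; best f% = 80
success clusters: k = 3, centers = [0.788, 0.87, 0.932]
```

Reading the numbers: the classifier separates held-out positive edges
from sampled non-edges almost perfectly once the co-expression score is
included (AUC 0.977), while the embedding-only ablation is at chance on
this corpus — at 240 labeled pairs the 64-dimensional embedding alone
has too little training signal, so the ablation gap isolates exactly
what GDPS contributes. Twenty-three diseases survive the temporal
holdout filters; their mean prediction probabilities fall into three
success levels whose centers (0.79, 0.87, 0.93) order the diseases by
how confidently their new genes are recovered.

The same stages are available as a CLI over TSV artifacts:

```bash
gdlink simulate    --config config.yaml --seed 1
gdlink build-graph --config config.yaml
gdlink make-labels --config config.yaml --seed 1
gdlink embed       --config config.yaml --seed 1
gdlink train       --config config.yaml --seed 1
gdlink evaluate    --config config.yaml
gdlink discover    --config config.yaml
gdlink cluster     --config config.yaml
```

## Layout

- `gdlink.tables_io` — readers/filters for the three input tables
- `gdlink.hetgraph` — typed heterogeneous graph, integration rule, G′
- `gdlink.gdps` — the prioritization score
- `gdlink.edge_sampling` — positive holdout + GDPS-guided negatives
- `gdlink.embedding` — biased walks + skip-gram embeddings
- `gdlink.link_classifier` — pair features, logistic model, metrics
- `gdlink.discovery` — temporal holdout, Overlap/Ratio, 1-D k-means, KW tests
- `gdlink.synthetic_data` — planted-structure generators
- `gdlink.pipeline` / `gdlink.cli` — orchestration

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
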