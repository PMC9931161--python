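# Methods

## Graph model

The heterogeneous graph `G(D, V, E)` has disjoint disease (`D`) and gene
(`V`) node sets and two undirected edge types. Gene–disease edges come
from the association table after filtering to rows typed `disease` with
semantic type *Disease or Syndrome*, then dropping diseases with fewer
than two distinct genes (a disease must be able to appear on both sides
of a train/test split). Gene–gene edges come from the tissue table:
only High-level, Approved-reliability calls observed in at least two
distinct cell types count as a (gene, tissue) association, and the genes
of each tissue form a clique. Co-tissue membership is treated as binary;
no edge weights and no minimum tissue size are applied.

On integration, a gene–gene edge survives only if at least one endpoint
is a gene of the gene–disease layer. Genes appearing solely in discarded
edges are dropped: with no disease context anywhere in their
neighborhood they cannot inform link prediction and only dilute walks.

Node-set disjointness is enforced by a validation error at graph
construction rather than by internally prefixing identifiers: the
invariant is the same, and unprefixed node ids keep serialized graphs,
embeddings and rankings directly readable. Edge removal (forming the
training graph `G′`) never deletes nodes, so every endpoint of a
held-out pair retains an embedding even if left isolated.

## Prioritization score

GDPS(g, d) is the mean of `Z[g, gᵢ]` over the genes `gᵢ` adjacent to
`d` in `G′` that are present in the similarity matrix `Z`. Design
choices at the coverage boundary:

- a **candidate** gene absent from `Z` scores 0 with a logged warning —
  0 is the same neutral sentinel used for gene–gene pairs, and it keeps
  such genes out of the preferentially-sampled negative pool;
- a **known** disease gene absent from `Z` is skipped from the mean
  rather than imputed as 0, which would bias every candidate's score
  toward zero by a constant fabricated term;
- a disease with *no* scoreable known gene raises a distinct error, so
  "no basis for a score" is never silently conflated with a true 0;
- if the scored gene is itself adjacent to the disease, its unit
  self-similarity joins the mean as-is. This situation cannot arise for
  labeled or candidate pairs (both are non-edges of the relevant graph)
  and is defined only for completeness.

## Labeled set

Per disease, `max(1, round(0.2 · degree))` association edges are held
out uniformly at random as positives (half-up rounding; the floor of
one guarantees every disease contributes, which is why degree-1
diseases were filtered out earlier). An equal number N of negatives is
drawn: N/2 uniform gene–gene non-edges, and N/2 gene–disease non-edges
taken round-robin over lexicographically ordered diseases, each disease
contributing its unused non-associated gene with the lowest GDPS (ties
broken by gene id). Determinism given (G, Z, seed) is deliberate — the
round-robin loop is otherwise underdetermined and untestable.

Negative candidacy is always checked against the **original** G, so a
held-out positive can never be relabeled negative. Non-adjacency counts
both edge types. The 70/30 train/test split is stratified by label and
both partitions are forced non-empty per class.

## Embeddings

Second-order biased walks: from state (prev, cur) the next neighbor x
of cur has unnormalized weight 1/P if x = prev, 1 if x is adjacent to
prev, and 1/Q otherwise. Defaults: 64 dimensions, walk length 5, 10
walks per node, P = Q = 1 (uniform first-order walking, fast path).
Walks treat the graph as homogeneous and untyped.

The skip-gram-with-negative-sampling model is trained in numpy:
vocabulary from the walks, negative-sampling distribution proportional
to unigram count^0.75, 5 negatives per pair, fixed context window 5
(window beyond the walk length is wasted), 5 epochs, linearly decaying
learning rate 0.025 → 1e-4, mini-batches of 1024 with accumulated
(hogwild-style) scatter updates. Single-threaded and bit-reproducible
given the seed. Isolated nodes enter the vocabulary via their length-1
walks and keep their near-random initialization — embeddings exist for
every node, which is the property the pipeline requires.

A pair (u, v) is represented as the element-wise sum u + v (symmetric
in argument order) with the pair's GDPS appended as a 65th feature.

## Classifier

L2-regularized logistic regression (C = 1.0, exposed), probability
threshold 0.5 for the link-formation class — balanced classes make 0.5
the natural operating point, and the discovery layer consumes raw
probabilities anyway. Features are not standardized by default
(embedding coordinates and GDPS are both O(1)); a switch exists for
sensitivity analysis. Evaluation reports micro-F1, precision and recall
at 0.5 plus trapezoidal ROC AUC; on balanced binary data micro-F1
coincides with accuracy. Model selection/comparison uses stratified
10-fold cross-validation on the train split.

## Discovery layer

The temporal holdout keeps associations first reported in the cutoff
year, in order: (1) year + disease-type filters; (2) diseases with ≥ 2
new genes; (3) pairs not already edges of G′; (4) genes with DSI above
the mean DSI and DPI below the mean DPI, means over distinct genes of
the full table (not association rows, which would weight promiscuous
genes by their edge count). Candidate rankings score every gene of G′
not adjacent to the disease; only link-formation-class predictions are
kept. The top-f% cutoff uses `ceil`, so P_f% is non-empty for any f ≥ 1.
Ratio's denominator is the percentage as a number (30, not 0.3); ties
on the maximum resolve to the smallest f.

Mean prediction probability per disease averages over the
link-formation-class candidates only — the set the pipeline actually
carries forward. Clustering of those means uses an exact O(k n²)
dynamic program (globally optimal within-cluster sum of squares per k)
with k selected by Gaussian-mixture BIC over 2–9. In the BIC, cluster
variances use the unbiased estimator and singleton or zero-variance
clusters fall back to the overall sample variance; without that
fallback the likelihood of shattering the data into tiny clusters is
unbounded and k runs to the top of the range. Constant input collapses
to a single reported cluster (k = 1, below the searched range) rather
than an arbitrary split. Cluster-to-Overlap-band mapping uses the
majority band of member diseases when overlaps are known ([0, 0.5] low,
(0.5, 1) mid, {1} high) and center rank order otherwise. Cluster
comparisons use Kruskal–Wallis, omnibus plus all pairwise, with no
multiplicity correction (flagged in the report output).

## Synthetic data

The generator emulates the three input tables with planted structure:
genes partitioned into co-expression modules; `Z` as within/between
module means (0.7 / 0.05) plus symmetrized Gaussian noise (SD 0.1),
clipped to [-1, 1] with unit diagonal; diseases drawing 90% of their
10–20 genes from one home module; tissues sampling genes from single
modules with 80% of calls emitted as High/Approved in two cell types;
30% of each disease's edges stamped with the future discovery year, and
future-edge genes biased so ~70% pass the DSI/DPI holdout filter.
Defaults: 500 genes, 5 modules, 40 diseases, 10 tissues — small enough
to run the full pipeline in seconds, large enough that co-expression is
genuinely informative about held-out edges.

`Z` is *not* forced positive semidefinite: the score reads entries
element-wise, so only the entry distribution matters. What the
generator does not emulate: realistic RNA-seq counts, identifier
mismatches between symbol systems, literature-curation biases, hub-gene
degree distributions, or diseases spanning many modules. Passing tests
therefore demonstrate correctness of the mechanics and recoverability
of a planted signal, not expected performance on real databases — where
coverage gaps between the association table and `Z` and far sparser
per-disease gene sets will matter.

## Problem sizes and numerics

End-to-end checks run the generator defaults over 10 seeds and the
sampling-invariant checks a 200-gene/20-disease configuration over 20
seeds — sizes chosen so the planted signal is comfortably detectable
while a full suite run stays in the tens of seconds. Matrix symmetry is
repaired silently only below 1e-9 asymmetry; anything larger errors.
Score equality checks use 1e-12 absolute tolerance. GDPS ties in
negative sampling and probability ties in rankings break
lexicographically by gene id.

## Known limitations

- The identifier spaces of the association and tissue tables are
  assumed pre-harmonized (or mapped by the user); no symbol conversion
  is performed.
- The embedding-only ablation is weak at desk scale (hundreds of
  labeled pairs vs 64 dimensions); on corpus-scale graphs the
  structural signal would carry more weight and the ablation gap would
  narrow.
- The success-cluster → Overlap-band mapping is derived from diseases
  whose overlaps are known; for genuinely novel diseases the rank-order
  fallback is a heuristic.
- Literature-based validation of predicted genes (querying publication
  databases) is out of scope.
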