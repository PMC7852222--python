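# Methods notes

## Model and assumptions

The package treats gene-function relevance as a network-proximity problem.
A gene's annotation is "relevant in context" when the gene and the GO term
occupy the same neighborhood of the GeneWalk network (GWN) — the graph
joining the input genes (gene–gene interaction edges), the GO ontology
(`is_a` edges only), and gene→term annotation edges. The GWN is undirected
and simple: multiple lines of evidence for one node pair collapse to a
single edge, so the degree d(n) counts distinct neighbors. The method
assumes the supplied interaction network is context-specific (it is built
from the input gene list only) and that ontology structure is meaningful
but not context-specific — which is why significance is judged against
degree-matched randomized networks rather than against no model at all.

Walk sampling starts d(n) walks of L = 10 nodes from every non-isolated
node and repeats the sweep N_iteration = 100 times, so the corpus holds
exactly N_iteration · Σ d(n) walks and every edge is traversed, in
expectation, equally often. Embeddings come from a skip-gram model with
k = 5 negative samples (noise ∝ unigram^{3/4}), window 1 (only directly
connected node pairs ever co-train), dim_rep = 8, no downsampling, no
minimum count. Isolated nodes receive no vector; their annotations are
reported as untested.

## Significance model

Null similarities are pooled from nreps_null configuration-model rewirings
of the full GWN edge set (self-loops dropped and multi-edges collapsed
afterwards; the resulting per-node degree distortion is monitored in tests
and averages < 0.5). Each rewired network is embedded by exactly the same
walk + training procedure, and every (node, neighbor) cosine similarity
enters the pool. The p-value of an observed similarity s is
(1 + #{null ≥ s}) / (1 + N): the add-one convention keeps p in (0, 1] and
counts ties against significance. BH-FDR is applied globally and per gene;
the real-GWN embedding is repeated nreps_graph times and the reported
gene/global p-adjust is the across-repeat mean with a Student-t 95% CI
(mean ± t₀.₉₇₅,ₙ₋₁ · s.e.m., clipped to [0, 1]; small repeat counts make
normal intervals anti-conservative). CI lower bounds may touch 0 after
clipping; point estimates stay strictly positive.

Seed derivation: null replicate j uses base_seed + j for rewiring, walks
and training; real-GWN repeat i uses base_seed + 100000 + i, keeping the
two streams disjoint.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| L | 10 nodes | walk length; short walks probe local neighborhoods |
| N_iteration | 100 | corpus sweeps; reproducibility of similarities |
| dim_rep | 8 | embedding dimension; similarity-variance sweet spot |
| window | 1 | only adjacent walk positions co-train |
| k_neg | 5 | negative samples per positive pair |
| epochs / alpha | 1 / 0.005 | training effort; see below |
| nreps_graph / nreps_null | 10 / 10 (fast: 3 / 3) | repeat counts |
| fdr_alpha | 0.1 | reporting threshold only, never baked into computation |

**Training effort.** The walk corpus already repeats each neighborhood 100
times, so a single epoch performs roughly 1800 gradient updates per edge
direction. On planted-structure validation data, recovery of community
signal degrades monotonically with further training: the fully converged
skip-gram solution approaches a rank-8 factorization of the edge-local
pointwise-mutual-information matrix, which (at desk-scale graphs) encodes
degree and adjacency noise at the expense of mesoscale community
similarity, while a gentle single pass behaves like an early-stopped,
diffusion-smoothed factorization. Hence the defaults epochs = 1,
alpha = 0.005 (linear decay to 10⁻⁴); both remain exposed in
`TrainingConfig`. Reproducibility is bit-exact for a fixed seed in
single-worker mode; multi-worker operation (the `--nproc` flag) is
documented as run-to-run variable.

## Synthetic fixtures: what they emulate, what they do not

`generate_fixture` plants a partition: modules of genes densely wired
within (p_in = 0.4) and sparsely between (p_out = 0.02), each module
annotated to 2 dedicated signal leaves of a 3-level, branching-3 ontology,
with a 0.3 per-gene rate of decoy annotations to other modules' signal
leaves. Signal leaves for different modules are drawn from disjoint
depth-2 parent families, so modules couple through the ontology only at
depth ≤ 1; within a module the two leaves may be siblings, which mirrors
how related functions cluster in the real ontology. The "null" preset
(Erdős–Rényi gene layer at p = 0.1, matching the default fixture's
gene-layer density; two uniformly random leaf annotations per gene) has no
planted structure and supports type-I checks.

Real GWNs differ in ways the fixtures do not capture: they are 100–1000×
larger, heavy-tailed in degree, and their annotation edges correlate with
ontology depth. Passing the planted-recovery tests therefore demonstrates
that the pipeline's machinery discriminates planted community structure
from a degree-matched null at desk scale — not that its sensitivity on
real data equals the measured value.

**Known limitation.** At the default fixture scale (180 nodes), the
configuration-model null acquires a heavy upper tail from chance
co-clustering in the rewired graphs, and planted signal similarities sit
only just above its 90th percentile. Aggregate sensitivity at
gene_padj < 0.1 consequently plateaus near 0.5 in fast mode (the planted
annotations are still ranked far above decoys: signal-vs-decoy AUROC
> 0.8, decoy false-call rate ≈ 0). An independent rank-8 spectral
embedding subjected to the same null does no better, indicating an
informational limit of the small graph rather than a training deficiency;
on larger networks the null's chance-clustering tail thins and recall
rises.

## Numerical and design choices

- **p-value rank convention**: ≥ with add-one smoothing (ties count
  against significance); standard permutation-test practice.
- **GO level**: shortest `is_a` path to the namespace root, computed by
  upward BFS; deterministic and cheap.
- **Gene identity in GAF files**: DB Object Symbol, case-sensitive, with
  an optional DB-Object-ID → symbol mapping for other namespaces.
- **SIF relations**: recorded as edge metadata, never used by walks; a SIF
  row joining a gene to a GO id is accepted as a user-injected annotation
  edge.
- **Obsolete terms**: parsed, flagged, excluded from the GWN; annotations
  to them dropped with a warning.
- **Kendall tau variant**: tau-b (tie-corrected), since both rankings are
  heavily tied; undefined cases resolve to 1 for the perfect tied
  all-relevant prediction and 0 otherwise.
- **Uniformity-test degrees of freedom**: the default df = x_max(x_max+3)/2
  treats each conditional multinomial as having x+1 free parameters;
  `df_mode="constrained"` subtracts the sum-to-one constraints
  (df = x_max(x_max+1)/2). The constrained count is the calibrated one —
  simulations under the null reject at ≈ nominal rate with it and
  conservatively below nominal with the default — so calibration tests use
  the constrained mode while the default preserves the published formula.
- **Output determinism**: nodes are sorted before walk sampling and
  rewiring, and the result table is sorted by gene, gene_padj, go_id, so
  results are invariant to input file ordering.
- **Degenerate inputs**: empty gene list, edgeless GWN, empty walk corpus
  and empty null distribution all fail fast with clear errors; a
  single-repeat run warns that CIs collapse to the point estimate.
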