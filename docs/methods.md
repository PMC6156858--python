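# Methods

This note documents the models and procedures `acidscreen` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where the underlying analysis left the
design open.

## Screen normalization and QC

A plate is a set of wells with three roles: `compound` (one compound per
well, single dose), `neg` (vehicle/DMSO, untreated viability) and `pos`
(a cytotoxic QC compound). Percent inhibition is the anchor normalization

    inhibition(x) = 100 · (μ_neg − x) / (μ_neg − μ_pos),

computed per plate from that plate's own control means — plates measured on
different days or readers then remain comparable. The quantity is invariant
under any common positive rescaling of signals and controls, and it is
deliberately unclamped: a compound more cytotoxic than the QC control
legitimately scores above 100% (the packaged confirmed-hit table contains
values of 110–117%).

Plate quality is the screening-window coefficient

    Z′ = 1 − 3(σ_pos + σ_neg) / |μ_pos − μ_neg|,

from the control wells only (sample standard deviations, ddof = 1). Z′ ≤ 1
always; Z′ ≥ 0.5 is the conventional "excellent assay" band, and negative
values mean overlapping control distributions. Equal control means make both
quantities undefined and raise a degenerate-plate error naming the plate.

Hits are compounds with inhibition strictly greater than the threshold
(default 70%). The strict inequality is a declared choice; boundary behavior
was not specified in the source analysis. The published confirmation table
also lists one compound at 66% — below the stated screen threshold; the
table is shipped as printed and the discrepancy left to the reader, while the
implementation applies the uniform strict rule.

## Dose–response confirmation

Viability (percent of untreated) over a dose series including 0 is fitted
with the four-parameter logistic

    v(d) = bottom + (top − bottom) / (1 + (d/IC50)^h),

by unweighted least squares on the viability scale. Because the objective is
multimodal in (IC50, h), the fit is multi-started: IC50 initialized on a
5-point geometric grid spanning the positive doses and the Hill slope over
{±1, ±2}; the lowest-RSS solution wins. IC50 is optimized as log(IC50) to
keep it positive, and a negative fitted Hill slope is canonicalized by the
exact reparameterization (top ↔ bottom, h → −h). At least 5 distinct doses
including 0 are required; a flat series raises a no-response error (no
finite IC50 exists); an IC50 outside [min positive dose, max dose] is
flagged as extrapolated and warned about, since the curve's midpoint was
never bracketed by data. On noiseless generator output all four parameters
are recovered to ≤ 1e-6 relative error; with viability noise of sd 3 the
median IC50 error over 100 replicates stays within 15%.

Selectivity across cell lines is reported as pairwise IC50 ratios from
converged fits, with a boolean "preferential for acid-adapted" flag when the
adapted line's IC50 is below the parental line's and both are below the
normal (non-cancer) line's.

## Term enrichment (classic Fisher)

- **Universe**: genes with CPM > 1 (strict) in at least 3 samples, where
  CPM(g, s) = 1e6 · count(g, s)/library_size(s). Both cutoffs configurable.
- **Study set**: genes with adjusted p < α (strict, default α = 0.05),
  intersected with the universe. The companion fold-change filter
  (|log2FC| > 1, i.e. fold change > 2 in either direction) is computed but
  does not gate the study set.
- **Propagation**: the true-path rule — a gene annotated to a term is
  annotated to every ancestor. Propagation is idempotent and performed once,
  before counting.
- **Test**: per term, the one-sided Fisher exact p-value of the 2×2 table
  (study∩term, study∖term; rest∩term, rest∖term), computed as the
  hypergeometric upper tail P(X ≥ k). Terms with fewer than 5 annotated
  *universe* genes (counted after propagation; the universe-based counting is
  a declared choice) are excluded before testing. Survivors are ranked by
  ascending p (ties broken by term id for bit-exact reproducibility) and
  truncated to the top 1000.
- **No multiple-testing correction** is applied to term p-values;
  significance is judged at raw p < α, matching the classic algorithm's
  reporting convention. This is a property of the method being reproduced,
  not a statistical recommendation.

## Community summarization of the term graph

The graph is the ontology subgraph induced by the significant terms plus all
their ancestors, edges directed child → parent. Ontology-derived subgraphs
are always weakly connected (every term reaches the root).

**Partitioning** minimizes the Reichardt–Bornholdt spin-glass Hamiltonian

    H(σ) = − Σ_{i<j} [A_ij − γ · k_i k_j / (2m)] · δ(σ_i, σ_j)

on the undirected simple view, with γ = 1 (the modularity-equivalent null
model) and at most 200 spin states. The optimizer is simulated annealing
with single-node label moves (geometric cooling, defaults t: 1 → 0.01,
factor 0.99, one sweep = |V| proposals), followed by a greedy descent that
alternates single-node moves with whole-community merges — merges escape the
common local minimum where joining two communities is downhill overall but
every intermediate single move is uphill. Five restarts by default; the
lowest-energy restart wins. On all ≤ 9-node graphs in the test suite this
reaches the exhaustive minimum over every set partition. Disconnected input
is partitioned per weakly-connected component with disjoint label ranges.
Labels are canonicalized (1..q, ordered by each community's smallest member),
so equal partitions compare equal regardless of annealing history.

**Representatives.** HITS authority scores are computed by power iteration
(a ← Aᵀh, h ← Aa, L2-normalized, stopping when the L1 change < 1e-10); the
fixed point is the dominant eigenvector of AᵀA. With child → parent edges,
authority accumulates on general, heavily referenced ancestor terms, which is
the intended "highest in-degree" reading. Each community's representative is
its maximal-authority member; exact ties are broken uniformly at random from
a dedicated RNG stream seeded by (global seed, community label), so adding or
removing one community never perturbs another's choice.

**Collapse.** Stage 1 contracts each community onto its representative,
keeping deduplicated directed cross-community edges and dropping self-loops.
Stage 2 re-attaches every significant term as a leaf with a single
membership edge to its community node. Member counts are conserved (they sum
to the input node count). Two conventions exist for the inter-community
edges — contraction of member edges versus edges only between
representatives that are each other's ancestors — and both readings are
implemented (`edge_mode = "contracted"` (default) or `"rep-ancestry"`);
neither is asserted as the original figure's intent. Export is GraphML plus
a hand-written DOT (no Graphviz Python bindings are required).

## Expression summaries

The variance-stabilizing transform is log2(CPM + 1): monotone in counts,
invariant to library size, and deliberately simpler than shrinkage-based
regularized-log transforms — downstream scaling, PCA and grouping are
transform-agnostic, and numeric equivalence with shrinkage transforms is
explicitly not claimed. Rows are scaled either to [0, 1] (min–max) or to
z-scores (mean 0, sd 1, sample sd as in R's `scale()`); constant rows are
zeroed and flagged rather than dropped. PCA uses the 500 most variable
genes, row-standardized, via SVD with a fixed sign convention (each
component's largest-magnitude gene loading is made positive), so coordinates
are deterministic and invariant to gene order. Community expression profiles
average the scaled rows of all genes annotated to any member term; a gene
annotated into several communities appears in each (deliberate duplication,
as a gene can serve several processes), and within-community heatmap order
comes from hierarchical clustering with Euclidean distance and average
linkage (a declared choice; the original tooling's defaults were
unspecified).

Note one systematic effect visible in synthetic data: when a large fraction
of genes is strongly up-regulated in one condition, CPM normalization pushes
every other gene's CPM in that condition down (compositional closure), so
"null" communities drift slightly negative. This is a property of
library-size normalization, not a bug.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their arguments including the seed
(bitwise-identical repeat calls). Default study conditions: a 1280-compound
single-dose screen in 96-well plates (88 compound wells + 4 negative + 4
positive control wells per plate, one compound per well), a positive control
knocking out 80% of viability (the QC compound left ~20% viability),
multiplicative log-normal well noise with CV 5%, a 70% hit threshold with
planted hits drawn from 85–120% inhibition (~4.3% of the library, matching a
55/1280 screen-stage hit rate) and inactive compounds from 0–40%; 4PL
dose–response curves over 0–15 µM; a rooted ontology DAG (single root,
child → parent edges, every term reaches the root); gene annotations to
leaf-ward terms with planted-term enrichment expressed as an odds ratio on
DE membership (the baseline rate is solved numerically so the overall DE
fraction is exact); and negative-binomial counts (var = μ + φμ²,
φ = 0.05) for 2 conditions × 3 replicates with DE genes shifted by 2^lfc in
condition 2. Adjusted p-values are assigned so that exactly the planted DE
genes pass α — the generator plants a clean decision boundary rather than
emulating a particular testing procedure.

Not emulated: pH-dependent uptake or any biochemical mechanism,
plate-position (edge) effects, read-level sequencing artifacts, correlated
gene expression beyond the planted shifts, the dependency structure of a
real GO graph (term sizes are roughly uniform within depth levels), and
realistic p-value distributions under the null of the DE test. Passing tests
therefore demonstrate correctness of the pipeline's computations and
recoverability of planted signals under these idealized conditions — not
performance on real screens, where edge effects, potency-independent
fluorescence artifacts and annotation bias all matter.

## Scales, seeds and numerical choices

The demo (and the acceptance script built on it) runs at a small scale chosen
to keep a full pipeline execution in seconds on one CPU: 300 compounds, a
200-term ontology with 8 planted leaf terms, 2000 genes (10% DE at odds 20),
and 2 × 3 samples. Planted terms are leaves because a shallow term's
propagated annotation set can cover most of the universe, leaving nothing to
over-represent — the same reason real enrichment results are dominated by
specific terms. A single global seed fans out to named per-stage streams
(CRC32 of the stage name mixed into a SeedSequence), every derived seed is
below 2^31, and reruns with the same configuration are byte-identical
(verified file by file in the tests).

Tolerances: 4PL noiseless recovery asserted at 1e-6 relative; Fisher
p-values vs exact rational enumeration at 1e-12 absolute; HITS authority vs
dense eigendecomposition at 1e-8 (the oracle comparison is restricted to
graphs whose dominant eigenvalue of AᵀA is simple, since otherwise the
eigenvector is not unique); spin-glass energies vs exhaustive minima at 1e-9.
Degenerate inputs (equal control means, flat dose–response, zero library
sizes, edgeless graphs, constant expression rows) raise typed errors or are
flagged, as documented per function.
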