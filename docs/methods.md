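# Methods

## Insertion classification

Gene models are stranded intervals with ordered, non-overlapping exons;
coordinates are 0-based half-open (BED convention) at every boundary, and an
insertion is a single base — the integration point of the gene-trap cassette.
The classification implements the standard gene-trap logic: an exonic
integration disrupts the transcript in either orientation (the splice
acceptor captures the transcript, and antisense exonic insertions still
interrupt the exon), an intronic integration disrupts only in sense
orientation, and intronic antisense insertions are silent. UTRs are treated
as exonic because the annotation carries exon intervals only; splice-acceptor
directionality beyond strand, and promoter/enhancer effects, are not modeled.

Counting decisions that the data model forces but the underlying protocol
leaves open:

* **Unit of evidence.** Distinct sites — deduplicated on
  (chromosome, position, strand, library) — are counted, not reads: read
  counts reflect clonal expansion and PCR, whereas each unique site is one
  independent integration event.
* **Overlapping genes.** An insertion mutagenic in several overlapping genes
  is counted for each of them, since every downstream test is per-gene and
  computed independently.
* **Unknown chromosomes.** Insertions on chromosomes absent from the
  annotation are classified intergenic with a warning rather than rejected.

## Per-gene enrichment

For each gene the 2×2 table (mutagenic sites in gene vs all other genes) ×
(selected vs control) is tested one-sided for enrichment in the selected
library; the p-value is the upper hypergeometric tail P(X ≥ a), computed by
scipy in log space, so it is exact at any margin size. q-values use the
Benjamini–Hochberg step-up procedure (the standard reading of "FDR-corrected
p-values"); the hit threshold defaults to q < 0.05 and is configurable.

The multiple-testing family defaults to genes with at least one mutagenic
site in either library: genes never observed carry no evidence either way
and would only dilute the correction. `universe="all"` restores the full
annotation. No gene-length bias correction or overdispersion modeling is
attempted; the test conditions on the observed library totals.

## Rescue network

Per-background hit lists are merged into a bipartite background ↔ gene
graph. A gene's *frequency* is its bipartite degree; its significance
aggregate is the **minimum q across the backgrounds where it is a hit** — a
conservative choice made because a plotted per-gene significance has no
unique definition across backgrounds; Fisher's combined p is available as an
alternative (`HitMatrix.combined_p`). All orderings are fully deterministic:
frequency descending, then min q ascending, then lexicographic gene id.

## Network propagation

Heat diffusion with loss on an undirected, simple interactome. Each step
adds one unit of heat to every seed node, spreads heat equally along edges
(column-stochastic W, W[i,j] = 1/deg(j)), and removes the fraction ρ from
every node. The iteration F⁺ = (1−ρ)(W·F + F₀) is a contraction for any
0 < ρ < 1 and converges to F* = (1−ρ)(I−(1−ρ)W)⁻¹F₀; at the fixed point the
total heat is |S|(1−ρ)/ρ, which serves as an internal conservation check.

Parameter choices:

* **ρ = 0.5** by default — the common insulated-diffusion choice; exposed as
  a flag since the appropriate loss depends on how local a neighborhood is
  wanted (larger ρ → more local).
* **Convergence** is declared when the max-norm step change drops below
  `tol = 1e-12` (cap 10⁴ iterations). The tolerance is deliberately much
  tighter than the 1e-8 accuracy claimed for the result: with max-norm
  stopping at τ the *summed* heat error can approach n·τ·(1−ρ)/ρ, so τ must
  shrink well below the target accuracy divided by the node count. At
  ρ = 0.5 the geometric contraction makes the extra iterations cheap
  (~13 more halvings).
* **Isolated nodes** are removed before propagation (under column
  normalization they would absorb heat unrecoverably), with a warning; seeds
  not present in the network are dropped with a warning rather than mapped
  through aliases.
* The dense **closed-form solve** is provided for graphs up to 2000 nodes as
  an independent cross-check of the iterative path.

The neighborhood is the induced subgraph on the top-N nodes (default
N = 1000) ranked by score descending, seeds first on ties, then node id —
a fully deterministic cutoff.

## Modularity clustering

Newman–Girvan modularity Q = Σ_c [L_c/m − (D_c/2m)²] is maximized by a
deterministic two-stage procedure: CNM-style greedy agglomeration from
singletons (merge the connected community pair with the largest ΔQ, ties
broken by the lexicographically smallest label pair), followed by
single-node refinement. Plain hill climbing gets trapped whenever escaping
a local optimum needs a temporarily worsening move (already on the 6-node
path), so the refinement is Kernighan–Lin-style: each pass moves every node
exactly once to its best alternative community, taking the globally best
move even when its gain is negative, and rolls back to the best partition
seen during the pass. The KL stage is O(passes · n · E) and is applied to
graphs up to 300 nodes; beyond that only greedy agglomeration plus
first-improvement local moves run. A stochastic move-based maximizer
(Louvain/Leiden) would reach slightly higher Q on large graphs but was
rejected in favor of bit-reproducible output; resolution is fixed at 1.
Cross-component merges never help Q, so connected components are handled
independently by construction. Edgeless graphs return singletons with
Q defined as 0.

## Over-representation analysis

Each cluster is tested against every gene set with the hypergeometric upper
tail P(X ≥ overlap) — algebraically the same one-sided Fisher tail as the
screen test, which the test suite checks numerically. Gene sets are
intersected with the universe first. The universe should be the node set of
the background interactome (that is how the neighborhood was derived) and is
passed explicitly. BH correction is applied **within a cluster across
sets**, not across clusters: each cluster's annotation is read as its own
family of hypotheses.

## Assay arithmetic

Laser-track accumulation: GFP channel
(I_damage − I_background)/(I_nucleoplasm − I_background) − 1; γH2AX channel
(I_damage − I_background) − (I_nucleoplasm − I_background) − 1. The γH2AX
form is a background-subtracted *difference* and is implemented exactly as
published despite its asymmetry with the GFP ratio; because the asymmetry
could be a transcription slip, `ratio_gh2ax=True` switches the γH2AX channel
to the ratio form. The GFP ratio requires nucleoplasm intensity above
background and is scale-invariant in the background-subtracted intensities.

TLR normalization: rel_mutEJ = mutEJ_raw/mutEJ_mock and
rel_HR = (HR_raw/HR_mock)/f_SG2. Only HR is divided by the S/G2 fraction:
homologous recombination requires a sister chromatid, so differences in
cycling confound HR but not end-joining.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical design* of a rescue screen:

* **Null insertion model** — an insertion is intergenic with probability
  0.2 (default) and otherwise falls in a gene chosen proportionally to its
  length, uniformly within the gene, with uniform strand. Length
  proportionality is the simplest defensible null; the true integration
  preference of a retroviral trap (promoter-proximal bias, chromatin state,
  mappability) is *not* modeled, so passing recovery tests demonstrates the
  statistics, not robustness to real-data biases.
* **Selection** — planted resistant genes have their intensity multiplied by
  λ ≥ 1; λ = 1 recovers the null exactly. The multiplicative form keeps the
  Fisher null/alternative clean; fixed-count spiking would not.
* **Defaults as study conditions** — 200 genes (2–10 kb, 2–8 exons, half
  intronic), a 50 000-insertion unselected control, 8 000 insertions per
  selected library, five backgrounds, λ = 30 for planted genes. At these
  sizes a planted gene expects several hundred selected-library sites
  against ~200 in the control — comfortably detectable, as in the original
  screen design where suppressors emerge with massive enrichment — while
  the suite and the acceptance script stay in the seconds range.
* **Interactome** — a planted-partition (stochastic block) model with
  gene-id node labels; edges are drawn per pair with a single config-seeded
  RNG stream, making every artifact bit-identical under a fixed seed.

Read-level NGS artifacts (LAM-PCR/inverse-PCR biases, mappability) are out
of scope; the pipeline starts from mapped integration sites.

## Numerical and degenerate-input conventions

Fisher and hypergeometric tails come from scipy's log-space implementation;
a = 0 gives p = 1 when a is the smallest feasible cell value. BH is
statsmodels' `fdr_bh`. Merge and move ties in clustering, ranking ties in
the rescue network, and cutoff ties in neighborhood extraction are all
broken lexicographically. Modularity is undefined (error) on edgeless
graphs when scored directly. Contingency tables, p-values, strands,
coordinates and probabilities are validated at module boundaries.
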