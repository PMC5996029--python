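# traprescue

Analysis toolkit for **haploid gene-trap synthetic-rescue screens**. In such a
screen, a near-haploid human cell line carrying a deleterious mutation (for
example a DNA-repair gene knockout) is mutagenized with a retroviral gene-trap
cassette and then drug-selected under conditions that kill the parental
mutant. Insertions that disrupt a *suppressor* gene let cells survive, so the
genes rescuing the phenotype are those whose mutagenic insertion counts are
enriched in the selected population relative to an unselected control library.
`traprescue` takes mapped integration sites from there to an interpreted
synthetic-rescue network.

## Pipeline

1. **Classification** — each insertion is mapped onto stranded gene models and
   called *mutagenic* (exonic in either orientation, or intronic in sense
   orientation), *silent* (intronic antisense) or *intergenic*; distinct
   mutagenic sites are counted per gene.
2. **Enrichment** — for each gene *g*, the 2×2 table
   (sites in *g* vs elsewhere) × (selected vs control) is tested with a
   one-sided Fisher exact test, p = P(X ≥ a) under the hypergeometric null;
   Benjamini–Hochberg q-values are computed across genes and hits called at
   q < 0.05.
3. **Rescue network** — hit lists from several mutational backgrounds are
   merged into a bipartite background ↔ gene graph; genes are ranked by
   rescue frequency (bipartite degree) and minimum q, and multi-background
   suppressors (frequency ≥ k) extracted.
4. **Network propagation** — seed genes diffuse heat over a protein–protein
   interactome with per-step loss ρ: F⁺ = (1−ρ)(W·F + F₀) with
   column-stochastic W, converging to
   F\* = (1−ρ)(I−(1−ρ)W)⁻¹F₀ with total heat |S|(1−ρ)/ρ. The top-N hottest
   nodes define the screen's network neighborhood.
5. **Clustering + ORA** — the neighborhood is partitioned by deterministic
   modularity maximization (greedy agglomeration with Kernighan–Lin-style
   refinement) and each cluster annotated by hypergeometric
   over-representation against GMT gene sets.
6. **Assay arithmetic** — the small quantification formulas for laser
   micro-irradiation tracks and Traffic Light Reporter assays.

A first-class synthetic-data module (`traprescue.simulate`) generates toy
genomes, control/selected insertion libraries with planted resistant genes,
planted-partition interactomes and gene-set collections, so the entire
pipeline can be exercised and validated without any external data.

## Worked example

Three simulated backgrounds share two planted suppressor genes (λ = 25):

```python
from traprescue import (SimulationConfig, generate_annotation, generate_screen_set,
    count_gene_insertions, score_screen, build_rescue_network, rank_top_genes,
    multi_background_genes)

cfg = SimulationConfig(
    n_genes=100, n_backgrounds=3, shared_planted=("G0012", "G0077"),
    n_control_insertions=20000, n_selected_insertions=4000,
    enrichment_factor=25.0, seed=7,
)
ann = generate_annotation(cfg)
control, selected, truth = generate_screen_set(ann, cfg)
ctl = count_gene_insertions(control, ann)
tables = [(bg, score_screen(count_gene_insertions(lib, ann), ctl))
          for bg, lib in selected.items()]
for bg, t in tables:
    print(bg, "hits:", ", ".join(t.loc[t.is_hit, "gene_id"]))
matrix, edges = build_rescue_network(tables)
print(rank_top_genes(matrix, n=5).to_string(index=False))
print("multi-background (k=2):", multi_background_genes(matrix, k=2))
```

prints

```
bg1 hits: G0012, G0077
bg2 hits: G0012, G0077
bg3 hits: G0012, G0077
gene_id  frequency         min_q
  G0012          3 2.882701e-300
  G0077          3 6.885363e-237
multi-background (k=2): ['G0012', 'G0077']
```

Both planted genes are recovered in every background with overwhelming
significance, no false gene reaches the multi-background list, and the
frequency column is each gene's degree in the bipartite rescue network.

The same stages are available from the shell via the `traprescue` console
script (`simulate`, `classify`, `enrich`, `network`, `propagate`, `cluster`,
`quant`); see `traprescue --help`.

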