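"""Synthetic inputs for the whole pipeline: toy genomes, insertion libraries,
planted-community interactomes and gene-set collections.

The generators emulate the design of a haploid gene-trap rescue screen:

* an unselected control library — insertions placed with intensity
  proportional to gene length plus a configurable intergenic fraction (a
  deliberately simple null; the real integration-site distribution of the
  retroviral trap, e.g. promoter-proximal bias, is not modeled);
* one selected library per mutational background — the same placement model
  except that planted resistant genes have their intensity multiplied by an
  enrichment factor λ ≥ 1 (drug selection enriches cells carrying disruptions
  in those genes);
* an interactome drawn from a planted-partition (stochastic block) model so
  community recovery can be scored against ground truth;
* gene-set collections containing each planted community block, for
  over-representation self-consistency checks.

Every generator draws from a single ``numpy`` Generator seeded from its
config; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .annotate import GeneModel, Insertion

__all__ = [
    "SimulationConfig",
    "InteractomeSpec",
    "generate_annotation",
    "generate_screen_pair",
    "generate_screen_set",
    "generate_interactome",
    "generate_gene_sets",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for a simulated rescue screen.

    Defaults describe a desk-scale screen: 200 genes on one chromosome,
    a 50k-insertion unselected control, 8k insertions per selected
    background, five backgrounds sharing planted resistant genes boosted
    λ=30-fold, and 20% of insertions falling between genes.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    exons_per_gene: tuple[int, int] = (2, 8)
    intron_fraction: float = 0.5
    intergenic_fraction: float = 0.2
    n_control_insertions: int = 50_000
    n_selected_insertions: int = 8_000
    planted_genes: tuple[str, ...] = ()
    enrichment_factor: float = 30.0
    n_backgrounds: int = 5
    shared_planted: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_control_insertions <= 0 or self.n_selected_insertions <= 0:
            raise ValueError("insertion counts must be positive")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor (λ) must be >= 1")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid gene_length_range")
        elo, ehi = self.exons_per_gene
        if not 0 < elo <= ehi:
            raise ValueError("invalid exons_per_gene range")
        if not 0 <= self.intron_fraction < 1:
            raise ValueError("intron_fraction must lie in [0, 1)")
        if not 0 <= self.intergenic_fraction < 1:
            raise ValueError("intergenic_fraction must lie in [0, 1)")
        if self.n_backgrounds <= 0:
            raise ValueError("n_backgrounds must be positive")


@dataclass(frozen=True)
class InteractomeSpec:
    """Planted-partition model: blocks of node ids with within/between
    edge probabilities 0 <= p_out < p_in <= 1."""

    communities: tuple[tuple[str, ...], ...]
    p_in: float = 0.9
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        all_nodes = [n for block in self.communities for n in block]
        if len(all_nodes) != len(set(all_nodes)):
            raise ValueError("community blocks must partition the node set")
        if not all(self.communities) or not self.communities:
            raise ValueError("communities must be non-empty blocks")

    @property
    def n_nodes(self) -> int:
        return sum(len(b) for b in self.communities)


def gene_id(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_annotation(
    config: SimulationConfig, chrom_length: int | None = None
) -> list[GeneModel]:
    """Non-overlapping stranded gene models with exons on one chromosome.

    Genes are laid out left to right with intergenic gaps sized so that the
    requested ``intergenic_fraction`` of the chromosome is gene-free.  Exon
    count and lengths are drawn per gene; introns fill the space between
    exons so that about ``intron_fraction`` of each multi-exon gene is
    intronic.  Single-exon genes have no intronic positions at all.

    Raises
    ------
    ValueError
        If an explicit ``chrom_length`` cannot accommodate the genes.
    """
    rng = np.random.default_rng(config.seed)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    total_genic = int(lengths.sum())
    f = config.intergenic_fraction
    needed = int(np.ceil(total_genic / (1 - f))) + config.n_genes + 1
    if chrom_length is None:
        chrom_length = needed
    elif chrom_length < needed:
        raise ValueError(
            f"chromosome of length {chrom_length} cannot hold {config.n_genes} "
            f"genes totalling {total_genic} bp plus gaps (need >= {needed})"
        )
    total_gap = chrom_length - total_genic
    # split the gap budget into n_genes+1 roughly equal spacers
    gaps = np.full(config.n_genes + 1, total_gap // (config.n_genes + 1))
    gaps[: total_gap % (config.n_genes + 1)] += 1

    genes: list[GeneModel] = []
    cursor = 0
    for i, length in enumerate(lengths):
        cursor += int(gaps[i])
        start, end = cursor, cursor + int(length)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=gene_id(i),
                chrom="chrS1",
                start=start,
                end=end,
                strand=strand,
                exons=_draw_exons(rng, start, end, config),
            )
        )
        cursor = end
    return genes


def _draw_exons(
    rng: np.random.Generator, start: int, end: int, config: SimulationConfig
) -> tuple[tuple[int, int], ...]:
    length = end - start
    n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    n_ex = min(n_ex, (length + 1) // 2)  # every exon and intron needs >= 1 bp
    if n_ex <= 1:
        return ((start, end),)
    exonic = max(n_ex, int(round(length * (1 - config.intron_fraction))))
    intronic = length - exonic
    if intronic < n_ex - 1:  # keep every intron at least 1 bp
        intronic = n_ex - 1
        exonic = length - intronic
    ex_sizes = _random_composition(rng, exonic, n_ex)
    in_sizes = _random_composition(rng, intronic, n_ex - 1)
    exons = []
    pos = start
    for k in range(n_ex):
        exons.append((int(pos), int(pos + ex_sizes[k])))
        pos += ex_sizes[k]
        if k < n_ex - 1:
            pos += in_sizes[k]
    # first exon starts at the gene start and the last ends at the gene end
    assert pos == end
    return tuple(exons)


def _random_composition(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` positive integers, uniformly at random."""
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    bounds = np.concatenate(([0], cuts, [total]))
    return list(np.diff(bounds).astype(int))


def generate_screen_pair(
    annotation: Sequence[GeneModel],
    config: SimulationConfig,
    library_control: str = "control",
    library_selected: str = "selected",
) -> tuple[list[Insertion], list[Insertion], dict]:
    """Draw a matched (control, selected) insertion-library pair.

    Control insertions fall in a gene with probability
    ``1 - intergenic_fraction``, choosing genes with intensity proportional
    to their length, uniform position within the gene and uniform strand; the
    rest land uniformly in intergenic space.  The selected library uses the
    identical model except the intensity of each planted gene is multiplied
    by λ (``enrichment_factor``), mimicking drug selection that enriches
    cells whose trapped gene confers resistance.

    Returns ``(control, selected, truth)`` where ``truth`` records the
    planted genes and λ.
    """
    rng = np.random.default_rng(config.seed)
    known = {g.gene_id for g in annotation}
    unknown = set(config.planted_genes) - known
    if unknown:
        raise KeyError(f"planted genes absent from annotation: {sorted(unknown)}")
    control = _draw_library(rng, annotation, config, {}, config.n_control_insertions, library_control)
    boost = {g: config.enrichment_factor for g in config.planted_genes}
    selected = _draw_library(rng, annotation, config, boost, config.n_selected_insertions, library_selected)
    truth = {
        "planted_genes": list(config.planted_genes),
        "enrichment_factor": config.enrichment_factor,
    }
    return control, selected, truth


def generate_screen_set(
    annotation: Sequence[GeneModel],
    config: SimulationConfig,
    private_planted: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[Insertion], dict[str, list[Insertion]], dict]:
    """One shared control plus one selected library per background.

    Every background plants ``config.shared_planted``; ``private_planted``
    optionally adds background-specific resistant genes.  Background ids are
    ``bg1..bgN``.  Per-background seeds are derived deterministically from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    known = {g.gene_id for g in annotation}
    bgs = [f"bg{i + 1}" for i in range(config.n_backgrounds)]
    private = {bg: tuple(private_planted.get(bg, ())) for bg in bgs} if private_planted else {bg: () for bg in bgs}
    for bg in bgs:
        unknown = (set(config.shared_planted) | set(private[bg])) - known
        if unknown:
            raise KeyError(f"planted genes absent from annotation: {sorted(unknown)}")

    control = _draw_library(rng, annotation, config, {}, config.n_control_insertions, "control")
    selected: dict[str, list[Insertion]] = {}
    truth: dict = {
        "enrichment_factor": config.enrichment_factor,
        "shared_planted": list(config.shared_planted),
        "planted_by_background": {},
    }
    for bg in bgs:
        planted = tuple(config.shared_planted) + private[bg]
        boost = {g: config.enrichment_factor for g in planted}
        selected[bg] = _draw_library(
            rng, annotation, config, boost, config.n_selected_insertions, bg
        )
        truth["planted_by_background"][bg] = list(planted)
    return control, selected, truth


def _draw_library(
    rng: np.random.Generator,
    annotation: Sequence[GeneModel],
    config: SimulationConfig,
    boost: Mapping[str, float],
    n_insertions: int,
    library: str,
) -> list[Insertion]:
    genes = list(annotation)
    weights = np.array(
        [g.length * boost.get(g.gene_id, 1.0) for g in genes], dtype=float
    )
    weights /= weights.sum()
    chrom_end = max(g.end for g in genes)
    # intergenic space as sorted gap intervals on the chromosome
    gaps = []
    cursor = 0
    for g in sorted(genes, key=lambda g: g.start):
        if g.start > cursor:
            gaps.append((cursor, g.start))
        cursor = max(cursor, g.end)
    gap_lens = np.array([e - s for s, e in gaps], dtype=float)

    genic = rng.random(n_insertions) >= config.intergenic_fraction
    gene_idx = rng.choice(len(genes), size=n_insertions, p=weights)
    if gaps:
        gap_idx = rng.choice(len(gaps), size=n_insertions, p=gap_lens / gap_lens.sum())
    strands = np.where(rng.random(n_insertions) < 0.5, "+", "-")
    u = rng.random(n_insertions)

    out: list[Insertion] = []
    for k in range(n_insertions):
        if genic[k] or not gaps:
            g = genes[gene_idx[k]]
            pos = g.start + int(u[k] * g.length)
        else:
            s, e = gaps[gap_idx[k]]
            pos = s + int(u[k] * (e - s))
        out.append(
            Insertion(
                chrom=genes[0].chrom,
                pos=min(pos, chrom_end - 1),
                strand=str(strands[k]),
                library=library,
            )
        )
    return out


def generate_interactome(spec: InteractomeSpec) -> nx.Graph:
    """Undirected simple planted-partition graph over the given node blocks.

    Each within-block pair is an edge with probability ``p_in`` and each
    between-block pair with probability ``p_out``; no self-loops, no
    duplicate edges.
    """
    rng = np.random.default_rng(spec.seed)
    g = nx.Graph()
    block_of: dict[str, int] = {}
    for b, block in enumerate(spec.communities):
        for n in block:
            g.add_node(n, block=b)
            block_of[n] = b
    nodes = [n for block in spec.communities for n in block]
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            p = spec.p_in if block_of[u] == block_of[v] else spec.p_out
            if rng.random() < p:
                g.add_edge(u, v)
    return g


def generate_gene_sets(
    gene_ids: Sequence[str],
    community_blocks: Sequence[Sequence[str]] = (),
    n_random_sets: int = 10,
    set_size_range: tuple[int, int] = (5, 30),
    seed: int = 0,
) -> dict[str, list[str]]:
    """GMT-style collection: one set per planted community plus random sets.

    Community sets are named ``community_1..K`` and contain exactly the block
    members; random sets draw without replacement from ``gene_ids``.
    """
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    lo, hi = set_size_range
    if not 0 < lo <= hi or hi > len(gene_ids):
        raise ValueError("invalid set_size_range for this gene universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for i, block in enumerate(community_blocks):
        if not block:
            raise ValueError("empty community block requested as a gene set")
        sets[f"community_{i + 1}"] = sorted(block)
    for j in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"random_{j + 1}"] = sorted(
            rng.choice(np.asarray(gene_ids, dtype=object), size=size, replace=False)
        )
    return sets
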