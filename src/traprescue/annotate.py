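"""Map gene-trap insertion sites onto gene models and classify their effect.

A retroviral gene-trap cassette disrupts a gene when it lands in a
transcriptionally productive position.  The classification rules are:

* exonic insertion, either strand        -> ``mutagenic``
* intronic insertion, sense orientation  -> ``mutagenic``
* intronic insertion, antisense          -> ``silent``
* outside every gene                     -> ``intergenic``

All coordinates are 0-based half-open (BED convention).  An insertion is a
single base (the integration point), not an interval.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "Insertion",
    "InsertionClass",
    "ClassifiedInsertion",
    "classify_insertion",
    "classify_library",
    "count_gene_insertions",
    "classification_summary",
]


class InsertionClass(str, Enum):
    MUTAGENIC = "mutagenic"
    SILENT = "silent"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with exon intervals on a chromosome.

    ``exons`` are (start, end) pairs, 0-based half-open, sorted,
    non-overlapping and contained in ``[start, end)``.  UTRs are treated as
    exonic: the annotation carries exon intervals only.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = self.start
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s}, {e}) outside gene span")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def is_exonic(self, pos: int) -> bool:
        """True if ``pos`` falls inside an exon of this gene."""
        starts = [s for s, _ in self.exons]
        i = bisect_right(starts, pos) - 1
        return i >= 0 and self.exons[i][0] <= pos < self.exons[i][1]


@dataclass(frozen=True)
class Insertion:
    """A gene-trap integration site: chromosome, base position, strand."""

    chrom: str
    pos: int
    strand: str
    library: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ClassifiedInsertion:
    insertion: Insertion
    gene_id: Optional[str]
    klass: InsertionClass

    def __post_init__(self) -> None:
        if (self.klass is InsertionClass.INTERGENIC) != (self.gene_id is None):
            raise ValueError("gene_id is None iff the insertion is intergenic")


def classify_insertion(ins: Insertion, gene: GeneModel) -> InsertionClass:
    """Classify an insertion that lies inside ``gene``.

    Exonic positions are mutagenic irrespective of orientation; intronic
    positions are mutagenic in sense orientation and silent in antisense.

    Raises
    ------
    ValueError
        If the insertion is not on the gene's chromosome inside its span.
    """
    if ins.chrom != gene.chrom or not gene.contains(ins.pos):
        raise ValueError(
            f"insertion {ins.chrom}:{ins.pos} lies outside gene "
            f"{gene.gene_id} ({gene.chrom}:{gene.start}-{gene.end})"
        )
    if gene.is_exonic(ins.pos):
        return InsertionClass.MUTAGENIC
    if ins.strand == gene.strand:
        return InsertionClass.MUTAGENIC
    return InsertionClass.SILENT


def _gene_trees(annotation: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in annotation:
        trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end, gene)
    return trees


def classify_library(
    library: Iterable[Insertion], annotation: Sequence[GeneModel]
) -> list[ClassifiedInsertion]:
    """Classify every insertion against every overlapping gene.

    An insertion overlapping several genes yields one record per gene (per-gene
    statistics are computed independently downstream).  Insertions on
    chromosomes absent from the annotation are classified intergenic with a
    warning.
    """
    trees = _gene_trees(annotation)
    missing: Counter[str] = Counter()
    out: list[ClassifiedInsertion] = []
    for ins in library:
        tree = trees.get(ins.chrom)
        if tree is None:
            missing[ins.chrom] += 1
            out.append(ClassifiedInsertion(ins, None, InsertionClass.INTERGENIC))
            continue
        hits = tree[ins.pos]
        if not hits:
            out.append(ClassifiedInsertion(ins, None, InsertionClass.INTERGENIC))
            continue
        for iv in sorted(hits, key=lambda iv: iv.data.gene_id):
            gene: GeneModel = iv.data
            out.append(ClassifiedInsertion(ins, gene.gene_id, classify_insertion(ins, gene)))
    if missing:
        warnings.warn(
            f"insertions on chromosomes absent from the annotation treated as "
            f"intergenic: {dict(missing)}",
            stacklevel=2,
        )
    return out


def count_gene_insertions(
    library: Sequence[Insertion], annotation: Sequence[GeneModel]
) -> pd.DataFrame:
    """Count distinct mutagenic insertion sites per gene.

    Duplicate sites — identical (chrom, pos, strand, library) — are counted
    once: the unit of evidence is a unique integration site, not a read.
    Every annotated gene appears in the output, including zero counts.

    Returns a DataFrame with columns ``gene_id``, ``library``, ``n_mutagenic``.
    """
    lib_ids = sorted({ins.library for ins in library}) or [""]
    unique_sites = list(dict.fromkeys(library))  # dedupe, keep first-seen order
    counts: Counter[tuple[str, str]] = Counter()
    for rec in classify_library(unique_sites, annotation):
        if rec.klass is InsertionClass.MUTAGENIC:
            counts[(rec.gene_id, rec.insertion.library)] += 1
    rows = [
        {"gene_id": g.gene_id, "library": lib, "n_mutagenic": counts.get((g.gene_id, lib), 0)}
        for g in annotation
        for lib in lib_ids
    ]
    return pd.DataFrame(rows, columns=["gene_id", "library", "n_mutagenic"])


def classification_summary(
    classified: Iterable[ClassifiedInsertion],
) -> Mapping[str, int]:
    """Tally of mutagenic / silent / intergenic records."""
    tally = Counter(rec.klass.value for rec in classified)
    return {k.value: tally.get(k.value, 0) for k in InsertionClass}
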