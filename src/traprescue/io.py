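"""Readers and writers for the plain-text formats the pipeline exchanges.

Gene models travel as BED12 (block structure = exons) or as a flat gene
table; insertion libraries as BED6 where the name column is the library id
and the interval is the single integration base; interactomes as 2-column
edge-list TSV; gene-set collections as GMT.  All coordinates on disk follow
the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .annotate import GeneModel, Insertion

__all__ = [
    "read_annotation_bed12",
    "write_annotation_bed12",
    "read_insertions_bed6",
    "write_insertions_bed6",
    "write_gene_table",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
]

_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def read_annotation_bed12(path: str | Path) -> list[GeneModel]:
    """Load gene models from a 12-column BED file (blocks are exons)."""
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    genes = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != int(row.blockCount) or len(offsets) != int(row.blockCount):
            raise ValueError(f"{row.name}: blockCount inconsistent with block lists")
        exons = tuple(
            (int(row.start) + off, int(row.start) + off + size)
            for off, size in zip(offsets, sizes)
        )
        genes.append(
            GeneModel(
                gene_id=str(row.name),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                exons=exons,
            )
        )
    return genes


def write_annotation_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            w.writerow(
                [g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                 g.start, g.end, 0, len(g.exons), sizes, offsets]
            )


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Flat TSV companion to the BED12: gene_id, chrom, start, end, strand."""
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
             "end": g.end, "strand": g.strand}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_insertions_bed6(path: str | Path) -> list[Insertion]:
    """Load insertion sites from BED6; the name column carries the library id."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        Insertion(chrom=str(r.chrom), pos=int(r.start), strand=str(r.strand),
                  library=str(r.name))
        for r in df.itertuples(index=False)
    ]


def write_insertions_bed6(insertions: Iterable[Insertion], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for ins in insertions:
            w.writerow([ins.chrom, ins.pos, ins.pos + 1, ins.library, 1, ins.strand])


def read_edge_list(path: str | Path) -> nx.Graph:
    """Undirected simple graph from a 2-column TSV (self-loops rejected)."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split("\t")[:2]
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted((sorted((str(a), str(b))) for a, b in g.edges)):
            fh.write(f"{u}\t{v}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sets[name])
            fh.write(f"{name}\tna\t{members}\n")
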