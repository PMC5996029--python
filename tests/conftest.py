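"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (exact Fraction enumeration, linear
scans, exhaustive partition search) and never share code with the package
implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pytest

from traprescue import GeneModel, Insertion


# ---------------------------------------------------------------- oracles


def fisher_enum(a: int, b: int, c: int, d: int) -> Fraction:
    """Upper-tail Fisher p by exact enumeration of all tables with the
    observed margins, as a Fraction (row = selected/control, column = gene/rest)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = Fraction(0)
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        if x >= a:
            p += Fraction(comb(col1, x) * comb(n - col1, row1 - x), comb(n, row1))
    return p


def bh_step_up(p_values) -> np.ndarray:
    """Reference BH q-values via the literal step-up recursion."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify_linear(ins: Insertion, genes: list[GeneModel]) -> list[tuple[str, str]]:
    """Brute-force classification: linear scan of every gene and exon."""
    out = []
    for g in genes:
        if ins.chrom != g.chrom or not (g.start <= ins.pos < g.end):
            continue
        exonic = any(s <= ins.pos < e for s, e in g.exons)
        if exonic or ins.strand == g.strand:
            out.append((g.gene_id, "mutagenic"))
        else:
            out.append((g.gene_id, "silent"))
    return out


def set_partitions(items):
    """All partitions of a sequence (Bell-number many; keep len(items) <= 8)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield part + [[first]]


def best_partition_bruteforce(g: nx.Graph) -> tuple[float, list[list]]:
    """Exhaustive modularity maximum over every partition of the node set."""
    m = g.number_of_edges()
    deg = dict(g.degree)
    best_q, best = -np.inf, None
    for part in set_partitions(sorted(g.nodes, key=str)):
        q = 0.0
        for block in part:
            bs = set(block)
            intra = sum(1 for u, v in combinations(block, 2) if g.has_edge(u, v))
            dsum = sum(deg[n] for n in bs)
            q += intra / m - (dsum / (2 * m)) ** 2
        if q > best_q:
            best_q, best = q, part
    return best_q, best


def random_connected_graph(n: int, rng: np.random.Generator) -> nx.Graph:
    """Largest connected component of a G(n, p) with p above the threshold."""
    p = min(1.0, 2.5 * np.log(max(n, 2)) / n)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    giant = max(nx.connected_components(g), key=len)
    return g.subgraph(giant).copy()


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two 3-cliques joined by a single bridge edge."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    return g


@pytest.fixture
def toy_gene() -> GeneModel:
    """A + strand gene with two exons [100,200) and [300,400) on chr1."""
    return GeneModel(
        gene_id="GENE1",
        chrom="chr1",
        start=100,
        end=400,
        strand="+",
        exons=((100, 200), (300, 400)),
    )


@pytest.fixture
def toy_annotation(toy_gene) -> list[GeneModel]:
    other = GeneModel(
        gene_id="GENE2",
        chrom="chr1",
        start=1000,
        end=1500,
        strand="-",
        exons=((1000, 1100), (1400, 1500)),
    )
    return [toy_gene, other]
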