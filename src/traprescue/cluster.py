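"""Modularity clustering of a network neighborhood and gene-set annotation.

The extracted neighborhood is partitioned into groups of highly interconnected
genes by deterministic modularity maximization: a CNM-style greedy
agglomeration (merge the community pair with the largest modularity gain,
lexicographic tie-break) followed by a deterministic single-node local-move
refinement.  Each cluster is then annotated by hypergeometric
over-representation analysis (ORA) against user-supplied gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .screen import bh_fdr

__all__ = ["Partition", "modularity_score", "cluster_graph", "ora_test", "annotate_clusters"]

_EPS = 1e-12
# KL refinement is O(passes * n * E); beyond this size only greedy + simple
# local moves are applied
_KL_MAX_NODES = 300


@dataclass(frozen=True)
class Partition:
    """Node -> community label mapping with its modularity Q."""

    labels: dict[Hashable, Hashable]
    q: float

    def communities(self) -> dict[Hashable, set]:
        comms: dict[Hashable, set] = {}
        for node, lab in self.labels.items():
            comms.setdefault(lab, set()).add(node)
        return comms


def modularity_score(g: nx.Graph, labels: Mapping[Hashable, Hashable]) -> float:
    """Newman-Girvan modularity of a partition.

    Q = sum_c [ L_c / m - (D_c / 2m)^2 ] where L_c is the number of edges
    inside community c, D_c its total degree and m the edge count.
    """
    if g.number_of_edges() == 0:
        raise ValueError("modularity is undefined on a graph with no edges")
    missing = set(g.nodes) - set(labels)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(map(str, missing))}")
    m = g.number_of_edges()
    intra: dict[Hashable, int] = {}
    deg: dict[Hashable, int] = {}
    for node, d in g.degree:
        lab = labels[node]
        deg[lab] = deg.get(lab, 0) + d
    for u, v in g.edges:
        if labels[u] == labels[v]:
            lab = labels[u]
            intra[lab] = intra.get(lab, 0) + 1
    return sum(
        intra.get(lab, 0) / m - (deg[lab] / (2 * m)) ** 2 for lab in deg
    )


def cluster_graph(g: nx.Graph, refine: bool = True) -> Partition:
    """Deterministic greedy modularity maximization.

    Starts from singleton communities, repeatedly merges the community pair
    with the largest positive modularity gain (ties broken by the
    lexicographically smallest label pair), then optionally sweeps
    single-node moves until no move improves Q.  Connected components are
    never merged (a cross-component merge always lowers Q), so components are
    effectively handled independently.
    """
    if any(u == v for u, v in g.edges):
        raise ValueError("graph must have no self-loops")
    nodes = sorted(g.nodes, key=str)
    if g.number_of_edges() == 0:
        return Partition(labels={n: n for n in nodes}, q=0.0)

    m = g.number_of_edges()
    # community state; labels are the lexicographically smallest member node
    label = {n: n for n in nodes}
    deg = {n: d for n, d in g.degree}
    cdeg = dict(deg)
    # between-community edge counts, keyed on sorted label pairs
    between: dict[tuple, int] = {}
    for u, v in g.edges:
        key = tuple(sorted((u, v), key=str))
        between[key] = between.get(key, 0) + 1

    while between:
        best_gain, best_key = -1.0, None
        for key, e_ij in between.items():
            i, j = key
            gain = e_ij / m - cdeg[i] * cdeg[j] / (2 * m * m)
            if gain > best_gain + _EPS or (
                abs(gain - best_gain) <= _EPS
                and (best_key is None or _pair_sort_key(key) < _pair_sort_key(best_key))
            ):
                best_gain, best_key = gain, key
        if best_gain <= _EPS:
            break
        i, j = best_key  # i is lexicographically smaller: absorbing label
        for n, lab in label.items():
            if lab == j:
                label[n] = i
        cdeg[i] += cdeg.pop(j)
        merged: dict[tuple, int] = {}
        for (a, b), e in between.items():
            a = i if a == j else a
            b = i if b == j else b
            if a == b:
                continue
            key = tuple(sorted((a, b), key=str))
            merged[key] = merged.get(key, 0) + e
        between = merged

    if refine:
        label = _local_moves(g, label, m)
        if g.number_of_nodes() <= _KL_MAX_NODES:
            label = _kl_refine(g, label, m)
    label = _canonical_labels(label)
    return Partition(labels=label, q=modularity_score(g, label))


def _pair_sort_key(key: tuple) -> tuple:
    return tuple(str(x) for x in key)


def _local_moves(
    g: nx.Graph, label: dict, m: int, max_passes: int = 100
) -> dict:
    """Deterministic single-node moves while any strictly increases Q."""
    label = dict(label)
    deg = {n: d for n, d in g.degree}
    for _ in range(max_passes):
        moved = False
        for v in sorted(g.nodes, key=str):
            comm_deg: dict = {}
            for n, lab in label.items():
                comm_deg[lab] = comm_deg.get(lab, 0) + deg[n]
            links: dict = {}
            for u in g[v]:
                links[label[u]] = links.get(label[u], 0) + 1
            cur = label[v]
            # candidate targets: neighbor communities plus a fresh singleton
            candidates = sorted(set(links) - {cur}, key=str)
            if comm_deg[cur] - deg[v] > 0:
                candidates.append(("__singleton__", v))
            best_gain, best_target = _EPS, None
            for target in candidates:
                gain = _move_gain(links, comm_deg, cur, target, deg[v], m)
                if gain > best_gain + _EPS:
                    best_gain, best_target = gain, target
            if best_target is not None:
                label[v] = best_target
                moved = True
        if not moved:
            break
    return label


def _move_gain(
    links: dict, comm_deg: dict, cur, target, d_v: int, m: int
) -> float:
    """Modularity change of moving a node with degree d_v from ``cur`` to
    ``target`` (which may be absent from ``comm_deg``: a fresh singleton)."""
    l_cur = links.get(cur, 0)
    l_tgt = links.get(target, 0)
    d_rest = comm_deg[cur] - d_v  # current community's degree without v
    d_tgt = comm_deg.get(target, 0)
    return (l_tgt - l_cur) / m - d_v * (d_tgt - d_rest) / (2 * m * m)


def _kl_refine(g: nx.Graph, label: dict, m: int, max_passes: int = 30) -> dict:
    """Kernighan-Lin-style refinement: each pass moves every node exactly once
    to its best alternative community (best move overall first, even if the
    gain is negative), then rolls back to the best partition seen during the
    pass.  Escapes the single-move local optima that plain hill climbing
    cannot leave, deterministically."""
    deg = {n: d for n, d in g.degree}
    label = dict(label)
    q = modularity_score(g, label)
    for _ in range(max_passes):
        work = dict(label)
        comm_deg: dict = {}
        for n, lab in work.items():
            comm_deg[lab] = comm_deg.get(lab, 0) + deg[n]
        locked: set = set()
        cur_q = q
        best_q, best_snapshot = q, None
        for _step in range(g.number_of_nodes()):
            best_move, best_gain = None, -np.inf
            for v in sorted(g.nodes, key=str):
                if v in locked:
                    continue
                links: dict = {}
                for u in g[v]:
                    links[work[u]] = links.get(work[u], 0) + 1
                cur = work[v]
                targets = sorted(set(links) - {cur}, key=str)
                if comm_deg[cur] - deg[v] > 0:  # leaving a non-empty community
                    targets.append(("__new__", v))
                for target in targets:
                    gain = _move_gain(links, comm_deg, cur, target, deg[v], m)
                    key = (str(v), str(target))
                    if gain > best_gain + _EPS or (
                        abs(gain - best_gain) <= _EPS
                        and best_move is not None
                        and key < (str(best_move[0]), str(best_move[1]))
                    ):
                        best_gain, best_move = gain, (v, target)
            if best_move is None:
                break
            v, target = best_move
            cur = work[v]
            work[v] = target
            comm_deg[cur] -= deg[v]
            if comm_deg[cur] == 0:
                del comm_deg[cur]
            comm_deg[target] = comm_deg.get(target, 0) + deg[v]
            locked.add(v)
            cur_q += best_gain
            if cur_q > best_q + _EPS:
                best_q, best_snapshot = cur_q, dict(work)
        if best_snapshot is None:
            break
        label, q = best_snapshot, best_q
    return label


def _canonical_labels(label: dict) -> dict:
    """Relabel each community by its lexicographically smallest member."""
    rep: dict = {}
    for node, lab in label.items():
        if lab not in rep or str(node) < str(rep[lab]):
            rep[lab] = node
    return {node: rep[lab] for node, lab in label.items()}


def ora_test(
    cluster_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in one cluster.

    For each set, p = P(X >= overlap) drawing ``|cluster|`` genes from a
    universe containing ``|set ∩ universe|`` set members; q-values are BH
    across the sets tested for this cluster.  Gene sets are intersected with
    the universe first; the cluster must be contained in the universe.

    Returns a DataFrame (set_name, overlap, set_size, cluster_size,
    universe_size, p, q) sorted by (q, p, set_name).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    cluster = set(cluster_genes)
    if not cluster <= uni:
        raise ValueError("cluster genes must be contained in the universe")
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & uni
        overlap = len(cluster & members)
        p = float(hypergeom.sf(overlap - 1, len(uni), len(members), len(cluster)))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(members),
                "cluster_size": len(cluster),
                "universe_size": len(uni),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["q", "p", "set_name"], kind="mergesort").reset_index(
            drop=True
        )
    return out


def annotate_clusters(
    partition: Partition,
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Run :func:`ora_test` for every community of a partition.

    The universe defaults conceptually to the background interactome's nodes
    (how the neighborhood was derived); pass it explicitly.
    """
    frames = []
    for lab, members in sorted(partition.communities().items(), key=lambda kv: str(kv[0])):
        t = ora_test(members, gene_sets, universe)
        t.insert(0, "cluster", str(lab))
        frames.append(t)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
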