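"""Heat diffusion with loss over an undirected interactome.

One unit of heat is injected at each seed node every step, spread equally to
neighbors, and a constant fraction rho is removed from every node, so total
heat is conserved at the stationary state.  The stationary heat of a node
measures its integrated network distance to the seed set.

With column-stochastic W (W[i, j] = 1/deg(j) for each edge i-j) and the seed
indicator F0, the iteration

    F_{t+1} = (1 - rho) * (W @ F_t + F0)

converges for any 0 < rho < 1 to

    F* = (1 - rho) * (I - (1 - rho) W)^{-1} @ F0,

with total heat sum(F*) = |seeds| * (1 - rho) / rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PropagationParams",
    "HeatVector",
    "normalize_adjacency",
    "propagate",
    "propagate_closed_form",
    "extract_neighborhood",
]

# above this size the dense closed form is avoided and only iteration is used
_CLOSED_FORM_MAX_NODES = 2000


@dataclass(frozen=True)
class PropagationParams:
    seeds: tuple[str, ...]
    rho: float = 0.5
    tol: float = 1e-12
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie strictly between 0 and 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not self.seeds:
            raise ValueError("seed set must be non-empty")


@dataclass(frozen=True)
class HeatVector:
    scores: pd.Series  # index = node ids, non-negative stationary heat
    converged: bool
    iterations: int
    seeds: tuple[str, ...]


def _validate_graph(g: nx.Graph) -> None:
    if any(u == v for u, v in g.edges):
        raise ValueError("interactome must have no self-loops")


def normalize_adjacency(g: nx.Graph) -> tuple[sparse.csr_array, list]:
    """Column-stochastic transition operator of a simple undirected graph.

    W[i, j] = 1 / degree(j) if i-j is an edge, else 0, so each column of a
    connected node sums to 1 (heat leaving a node splits equally among its
    neighbors).  Zero-degree nodes would absorb heat unrecoverably and are
    removed with a warning.

    Returns ``(W, nodes)`` with ``nodes`` the retained node order.
    """
    _validate_graph(g)
    isolated = sorted(nx.isolates(g))
    if isolated:
        warnings.warn(
            f"removing {len(isolated)} isolated node(s) before propagation",
            stacklevel=2,
        )
        g = g.subgraph(n for n in g if n not in set(isolated))
    nodes = sorted(g.nodes)
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=float)
    deg = np.asarray(a.sum(axis=0)).ravel()
    w = a @ sparse.diags_array(1.0 / deg)
    return w.tocsr(), nodes


def propagate(g: nx.Graph, params: PropagationParams) -> HeatVector:
    """Iterate the lossy diffusion to its stationary heat vector.

    Convergence is declared when the max-norm change between iterations drops
    below ``params.tol``; for rho > 0 the iteration is a contraction and a
    failure to converge within ``max_iter`` (reported via ``converged=False``)
    can only indicate a numerical problem.
    """
    w, nodes = normalize_adjacency(g)
    node_set = set(nodes)
    dropped = [s for s in params.seeds if s not in node_set]
    if dropped:
        warnings.warn(
            f"seed(s) absent from the interactome dropped: {sorted(dropped)}",
            stacklevel=2,
        )
    seeds = tuple(s for s in params.seeds if s in node_set)
    if not seeds:
        raise ValueError("no seeds remain after isolated-node removal")

    idx = {n: i for i, n in enumerate(nodes)}
    f0 = np.zeros(len(nodes))
    f0[[idx[s] for s in seeds]] = 1.0
    retain = 1.0 - params.rho

    f = np.zeros_like(f0)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        f_next = retain * (w @ f + f0)
        if np.max(np.abs(f_next - f)) < params.tol:
            f = f_next
            converged = True
            break
        f = f_next
    return HeatVector(
        scores=pd.Series(f, index=nodes),
        converged=converged,
        iterations=iterations,
        seeds=seeds,
    )


def propagate_closed_form(g: nx.Graph, params: PropagationParams) -> pd.Series:
    """Stationary heat via the dense linear solve (graphs up to ~2000 nodes).

    Cross-check for :func:`propagate`: solves
    (I - (1 - rho) W) F = (1 - rho) F0 directly.
    """
    w, nodes = normalize_adjacency(g)
    if len(nodes) > _CLOSED_FORM_MAX_NODES:
        raise ValueError(
            f"closed form limited to {_CLOSED_FORM_MAX_NODES} nodes; use propagate()"
        )
    node_set = set(nodes)
    seeds = [s for s in params.seeds if s in node_set]
    if not seeds:
        raise ValueError("no seeds present in the graph")
    idx = {n: i for i, n in enumerate(nodes)}
    f0 = np.zeros(len(nodes))
    f0[[idx[s] for s in seeds]] = 1.0
    retain = 1.0 - params.rho
    m = np.eye(len(nodes)) - retain * w.toarray()
    f = np.linalg.solve(m, retain * f0)
    return pd.Series(f, index=nodes)


def extract_neighborhood(
    heat: HeatVector, g: nx.Graph, n: int = 1000
) -> nx.Graph:
    """Induced subgraph on the ``n`` hottest nodes.

    Nodes are ranked by (score desc, seed first, node id) so ties at the
    cutoff are broken deterministically.  ``n`` larger than the scored node
    count returns the whole scored graph with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scored = heat.scores
    if n > len(scored):
        warnings.warn(
            f"top-n={n} exceeds the {len(scored)} scored nodes; returning all",
            stacklevel=2,
        )
        n = len(scored)
    seed_set = set(heat.seeds)
    order = sorted(
        scored.index, key=lambda v: (-scored[v], v not in seed_set, str(v))
    )
    return g.subgraph(order[:n]).copy()
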