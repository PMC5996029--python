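"""Cross-background synthetic-rescue network.

Each screened mutational background contributes a hit list (genes whose loss
rescued that background's drug sensitivity).  The integrated object is a
bipartite background <-> gene graph; a gene's degree is the number of
backgrounds it rescues, and its significance is summarised as the smallest
q-value across backgrounds (conservative; Fisher's combined p is offered as an
alternative aggregate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import combine_pvalues

__all__ = [
    "HitMatrix",
    "build_rescue_network",
    "multi_background_genes",
    "rank_top_genes",
]


@dataclass(frozen=True)
class HitMatrix:
    """Boolean hit calls and q-values, genes x backgrounds."""

    hit: pd.DataFrame  # bool, index=gene_id, columns=backgrounds
    q: pd.DataFrame  # float, same shape; NaN where the gene was not tested

    @property
    def backgrounds(self) -> list[str]:
        return list(self.hit.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.hit.index)

    def frequency(self) -> pd.Series:
        """Number of backgrounds each gene rescues (its bipartite degree)."""
        return self.hit.sum(axis=1).astype(int)

    def min_q(self) -> pd.Series:
        """Smallest q across backgrounds where the gene is a hit."""
        return self.q.where(self.hit).min(axis=1)

    def combined_p(self) -> pd.Series:
        """Fisher's combined p across the backgrounds where the gene is a hit."""
        vals = {}
        for gene in self.hit.index:
            qs = self.q.loc[gene][self.hit.loc[gene]].dropna()
            vals[gene] = (
                combine_pvalues(qs, method="fisher").pvalue if len(qs) else np.nan
            )
        return pd.Series(vals)


def build_rescue_network(
    hits_per_background: Sequence[tuple[str, pd.DataFrame]],
) -> tuple[HitMatrix, list[tuple[str, str]]]:
    """Integrate per-background enrichment tables into the rescue network.

    Parameters
    ----------
    hits_per_background
        ``(background_id, table)`` pairs where each table has ``gene_id``,
        ``q`` and ``is_hit`` columns (the output of
        :func:`traprescue.screen.score_screen`).

    Returns
    -------
    (matrix, edges)
        The gene x background :class:`HitMatrix` restricted to genes hit in at
        least one background, and the bipartite edge list
        ``[(background, gene), ...]`` in deterministic order.
    """
    if not hits_per_background:
        raise ValueError("at least one background required")
    bgs = [bg for bg, _ in hits_per_background]
    if len(set(bgs)) != len(bgs):
        raise ValueError(f"duplicate background ids: {bgs}")

    hit_cols, q_cols = {}, {}
    for bg, table in hits_per_background:
        t = table.set_index("gene_id")
        hit_cols[bg] = t["is_hit"].astype(bool)
        q_cols[bg] = t["q"].astype(float)
    genes = sorted(set().union(*(s.index for s in hit_cols.values())))
    hit = pd.DataFrame(
        {bg: s.reindex(genes, fill_value=False) for bg, s in hit_cols.items()}
    )
    q = pd.DataFrame({bg: s.reindex(genes) for bg, s in q_cols.items()})

    any_hit = hit.any(axis=1)
    hit, q = hit[any_hit].sort_index(), q[any_hit].sort_index()
    matrix = HitMatrix(hit=hit, q=q)
    edges = [
        (bg, gene) for bg in matrix.backgrounds for gene in hit.index[hit[bg]]
    ]
    return matrix, edges


def multi_background_genes(matrix: HitMatrix, k: int = 2) -> list[str]:
    """Genes rescuing at least ``k`` backgrounds.

    Sorted by (frequency desc, min q asc, gene id) for a fully deterministic
    ordering.  ``k`` larger than the number of backgrounds yields an empty
    list with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix.backgrounds):
        warnings.warn(
            f"k={k} exceeds the number of backgrounds "
            f"({len(matrix.backgrounds)}); no gene can qualify",
            stacklevel=2,
        )
        return []
    summary = rank_top_genes(matrix, n=len(matrix.genes))
    return summary.loc[summary["frequency"] >= k, "gene_id"].tolist()


def rank_top_genes(matrix: HitMatrix, n: int = 10) -> pd.DataFrame:
    """Top ``n`` rescue genes by (frequency desc, min q asc, gene id).

    Returns a DataFrame with columns gene_id, frequency, min_q.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    summary = pd.DataFrame(
        {
            "gene_id": matrix.genes,
            "frequency": matrix.frequency().to_numpy(),
            "min_q": matrix.min_q().to_numpy(),
        }
    )
    summary = summary.sort_values(
        ["frequency", "min_q", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return summary.head(n)
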