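"""Per-gene enrichment of a selected insertion library over an unselected control.

For each gene a 2x2 table of mutagenic insertion-site counts is built

    a = sites in the gene, selected library
    b = sites in all other genes, selected
    c = sites in the gene, control
    d = sites in all other genes, control

and the one-sided Fisher exact test (alternative: enrichment in the selected
library) gives a p-value, corrected across genes by the Benjamini-Hochberg
step-up procedure into q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["ContingencyTable", "fisher_one_sided", "bh_fdr", "score_screen"]


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def fisher_one_sided(table: ContingencyTable | tuple[int, int, int, int]) -> float:
    """One-sided Fisher exact p-value for enrichment of ``a``.

    The p-value is the upper hypergeometric tail P(X >= a) in a population of
    ``a+b+c+d`` items with ``a+c`` in the gene's class, drawing ``a+b`` (the
    selected library).  The tail is evaluated in log space by scipy and is
    exact at any table size.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j>=i} ( m * p_(j) / j ) on the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_screen(
    selected: Mapping[str, int] | pd.DataFrame,
    control: Mapping[str, int] | pd.DataFrame,
    q_threshold: float = 0.05,
    universe: Literal["observed", "all"] = "observed",
) -> pd.DataFrame:
    """Per-gene Fisher enrichment of selected over control counts.

    Parameters
    ----------
    selected, control
        Per-gene mutagenic site counts over the same gene universe: either a
        mapping ``gene_id -> count`` or a DataFrame with ``gene_id`` and
        ``n_mutagenic`` columns (as produced by
        :func:`traprescue.annotate.count_gene_insertions`).
    q_threshold
        Genes with q below this are flagged as hits.
    universe
        ``"observed"`` (default) restricts the multiple-testing family to genes
        with at least one mutagenic site in either library — genes never
        observed carry no evidence and would only dilute the correction.
        ``"all"`` keeps every gene.

    Returns
    -------
    DataFrame with columns gene_id, a, b, c, d, p, q, is_hit, sorted by
    (q, p, gene_id).
    """
    sel = _as_count_series(selected)
    ctl = _as_count_series(control)
    if set(sel.index) != set(ctl.index):
        raise KeyError("selected and control cover different gene universes")
    ctl = ctl.reindex(sel.index)

    if universe == "observed":
        keep = (sel > 0) | (ctl > 0)
        sel, ctl = sel[keep], ctl[keep]
    elif universe != "all":
        raise ValueError("universe must be 'observed' or 'all'")
    if sel.empty:
        return pd.DataFrame(
            columns=["gene_id", "a", "b", "c", "d", "p", "q", "is_hit"]
        )

    tot_sel, tot_ctl = int(sel.sum()), int(ctl.sum())
    a = sel.to_numpy(dtype=int)
    c = ctl.to_numpy(dtype=int)
    b = tot_sel - a
    d = tot_ctl - c
    # vectorized upper hypergeometric tail, one call for all genes
    p = hypergeom.sf(a - 1, tot_sel + tot_ctl, a + c, tot_sel)
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "gene_id": sel.index,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "p": p,
            "q": q,
            "is_hit": q < q_threshold,
        }
    )
    return out.sort_values(["q", "p", "gene_id"], kind="mergesort").reset_index(drop=True)


def _as_count_series(counts: Mapping[str, int] | pd.DataFrame) -> pd.Series:
    if isinstance(counts, pd.DataFrame):
        s = counts.set_index("gene_id")["n_mutagenic"]
    else:
        s = pd.Series(dict(counts), dtype=int)
    if s.index.has_duplicates:
        raise ValueError("duplicate gene ids in count table")
    if (s < 0).any():
        raise ValueError("counts must be non-negative")
    return s.astype(int)
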