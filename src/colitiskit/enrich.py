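"""Over-representation analysis (hypergeometric test + Benjamini–Hochberg).

Given a query gene set (e.g. formula targets shared with a disease), a GMT
collection of annotated terms and a background universe, each term is scored
with the one-sided hypergeometric upper tail and adjusted per category
(BP / CC / MF / pathway) by the BH step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "GeneSetTerm",
    "hypergeom_pvalue",
    "bh_adjust",
    "enrich_gene_set",
]

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass
class GeneSetTerm:
    name: str
    category: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.name!r} has an empty member set")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"term {self.name!r}: category {self.category!r} not in {CATEGORIES}"
            )


@dataclass
class GeneSetCollection:
    """``term_id -> GeneSetTerm`` mapping (unique term ids enforced by dict)."""

    terms: dict[str, GeneSetTerm] = field(default_factory=dict)

    def universe(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return out


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail ``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``.

    ``N`` universe size, ``K`` term size, ``n`` query size, ``k`` observed
    overlap.  Stable for ``N`` up to at least 1e5 (survival function in
    log-space inside scipy).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_gene_set(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric ORA of ``query`` against every term with >= 1 hit.

    BH adjustment is applied separately within each category; a term is
    flagged significant iff ``p_adj < alpha``.  Query genes outside the
    universe are dropped with a warning.  Columns: ``term_id, term_name,
    category, k, K, n, N, p, p_adj, significant``, sorted by
    ``(category, p_adj, p, term_id)``.
    """
    if universe is None:
        universe = collection.universe()
    if not universe:
        raise ValueError("empty universe")
    stray = set(query) - set(universe)
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe were dropped"
        )
    q = set(query) & set(universe)

    rows = []
    N, n = len(universe), len(q)
    for term_id, term in collection.terms.items():
        members = term.genes & universe
        k = len(q & members)
        if k == 0:
            continue  # k=0 terms are excluded from output and the BH family
        K = len(members)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term.name,
                "category": term.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_pvalue(k, K, n, N),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p"],
    )
    if df.empty:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["p_adj"] = np.nan
    for cat, idx in df.groupby("category").groups.items():
        df.loc[idx, "p_adj"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    return df.sort_values(
        ["category", "p_adj", "p", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
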