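"""Functional-category over-representation (hypergeometric test).

A generic stand-in for catalogue-based enrichment tools: given a query gene
set, a universe, and a user-supplied gene -> categories map, each category is
scored with the one-sided upper-tail hypergeometric P of drawing at least the
observed number of annotated genes in a query of that size. Genes without
any annotation stay in the universe (they affect N only). A Benjamini-
Hochberg column is provided for convenience.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .types import EnrichmentRecord


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def category_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    bh: bool = True,
) -> list[EnrichmentRecord]:
    """Score every category present in the universe; sorted ascending by P.

    ``annotation`` maps gene id -> iterable of category labels and may cover
    only a subset of the universe.
    """
    query = set(query)
    universe = set(universe)
    outside = query - universe
    if outside:
        raise ValidationError(
            f"query genes outside the universe: {sorted(outside)[:5]}"
        )
    members: dict[str, set[str]] = {}
    for gene, cats in annotation.items():
        if gene not in universe:
            continue
        for cat in cats:
            members.setdefault(cat, set()).add(gene)

    N = len(universe)
    n = len(query)
    records = []
    for cat in sorted(members):
        genes = members[cat]
        K = len(genes)
        k = len(genes & query)
        records.append(
            EnrichmentRecord(
                category=cat, k=k, K=K, n=n, N=N,
                p_value=hypergeom_upper_tail(k, K, n, N),
            )
        )
    records.sort(key=lambda r: (r.p_value, r.category))
    if bh and records:
        _, p_bh, _, _ = multipletests(
            [r.p_value for r in records], method="fdr_bh"
        )
        for r, adj in zip(records, p_bh):
            r.p_bh = float(adj)
    return records
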