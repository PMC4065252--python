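"""Reverse eQTL scan and expression-expression correlation.

The forward GWAS asks which SNPs track a gene's expression; the reverse scan
asks which genes' expression tracks a focal SNP's genotype. Each gene is
compared between the two haploid genotype classes with the two-sided
Mann-Whitney test (exact by enumeration for small tie-free samples, the
tie-corrected normal approximation otherwise), and family-wise significance
reuses the same permutation min-P scheme as the forward scan, shuffling
genotype labels and minimising over genes.

Gene-gene co-expression uses Spearman rank correlation, robust to the strong
right skew of RPKM values.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, PreconditionError
from .types import (
    MISSING,
    EqtlRecord,
    ExpressionMatrix,
    GenotypeMatrix,
    Locus,
    PermutationResult,
)

log = logging.getLogger(__name__)

_EXACT_MAX_N = 12


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U, P) with U = min(U1, U2).

    The exact null distribution (enumeration over rank arrangements) is used
    when n1 + n2 <= 12 and the pooled values are tie-free; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise PreconditionError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    exact = pooled.size <= _EXACT_MAX_N and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return u, float(res.pvalue)


def genotype_expression_test(
    locus: Locus, gene: str, G: GenotypeMatrix, expr: ExpressionMatrix
) -> EqtlRecord:
    """Mann-Whitney comparison of a gene's expression between the carriers of
    the locus's two alleles; direction is called from the group medians."""
    x1, x2 = _split_by_allele(locus, gene, G, expr)
    u, p = mann_whitney(x1, x2)
    med1, med2 = float(np.median(x1)), float(np.median(x2))
    if med1 > med2:
        higher = locus.alleles[0]
    elif med2 > med1:
        higher = locus.alleles[1]
    else:
        higher = None
    return EqtlRecord(
        locus=locus,
        gene=gene,
        n_per_genotype=(x1.size, x2.size),
        u_statistic=u,
        p_value=p,
        higher_expression_allele=higher,
    )


def _split_by_allele(locus, gene, G, expr):
    values = expr.row(gene)
    expr_idx = {s: j for j, s in enumerate(expr.strains)}
    calls = G.locus_calls(locus.id)
    if not locus.is_biallelic:
        raise PreconditionError(f"locus {locus.id} is not bi-allelic")
    groups: dict[str, list[float]] = {a: [] for a in locus.alleles}
    for strain, call in zip(G.strains, calls):
        if call == MISSING or strain not in expr_idx:
            continue
        groups[call].append(values[expr_idx[strain]])
    x1 = np.array(groups[locus.alleles[0]], dtype=float)
    x2 = np.array(groups[locus.alleles[1]], dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise DegenerateDataError(
            f"locus {locus.id}: a genotype class is empty among strains with "
            f"expression data"
        )
    return x1, x2


def reverse_gwas(
    locus: Locus,
    G: GenotypeMatrix,
    expr: ExpressionMatrix,
    b: int = 1000,
    seed: int = 0,
) -> tuple[list[EqtlRecord], PermutationResult | None]:
    """Test the focal SNP against every gene's expression.

    Returns one record per gene (in expression-table order) and, for b >= 1,
    the permutation null of per-shuffle minimum P-values obtained by
    shuffling genotype labels across strains and minimising over genes.
    With b = 0 no significance call is made.
    """
    records = [
        genotype_expression_test(locus, gene, G, expr) for gene in expr.genes
    ]
    if b < 1:
        log.warning("reverse_gwas called with B=%d: no significance call", b)
        return records, None

    # shared strains with a non-missing call, in expression-column order
    calls_by_strain = dict(zip(G.strains, G.locus_calls(locus.id)))
    cols, is_allele1 = [], []
    for j, strain in enumerate(expr.strains):
        call = calls_by_strain.get(strain, MISSING)
        if call == MISSING:
            continue
        cols.append(j)
        is_allele1.append(call == locus.alleles[0])
    values = expr.values[:, cols]
    n1 = int(np.sum(is_allele1))
    rng = np.random.default_rng(seed)
    min_p = np.empty(b)
    for i in range(b):
        order = rng.permutation(len(cols))
        g1 = values[:, order[:n1]]
        g2 = values[:, order[n1:]]
        res = stats.mannwhitneyu(
            g1, g2, alternative="two-sided", method="asymptotic", axis=1
        )
        min_p[i] = float(np.min(res.pvalue))
    return records, PermutationResult(b=b, min_p=min_p, seed=seed)


def significant_eqtl(
    records: list[EqtlRecord], perm: PermutationResult
) -> list[EqtlRecord]:
    """Apply the literal min-P removal rule to the reverse scan."""
    return [r for r in records if r.p_value <= perm.cutoff]


def expression_correlation(
    expr: ExpressionMatrix, gene_a: str, gene_b: str
) -> tuple[float, float]:
    """Spearman rank correlation between two genes across strains."""
    x = expr.row(gene_a)
    y = expr.row(gene_b)
    if x.size < 3:
        raise PreconditionError("expression_correlation requires >= 3 strains")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateDataError(
            "rank correlation is undefined for a constant expression vector"
        )
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
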