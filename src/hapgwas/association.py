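"""Per-SNP Fisher exact association between allele and resistance bin.

Each curated SNP is tested, in turn, for co-inheritance with the binary
high/low phenotype via the two-sided Fisher exact test: P is the sum of
hypergeometric point probabilities (fixed margins) of every 2x2 table as or
less probable than the observed one. The test is computed from a per-margin
lookup table so the permutation scan can reuse it cheaply.

Floating-point note: tables tied in point probability with the observed one
must be included in the two-sided sum. Point masses are computed in double
precision, so ties are detected with a 1e-10 relative tolerance — far below
the smallest relative gap between *distinct* hypergeometric point masses at
the population sizes involved (~6e-9 at N = 30), hence exact ties and only
exact ties are captured.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PreconditionError
from .types import (
    HIGH,
    LOW,
    MISSING,
    AssociationRecord,
    BinaryPhenotype,
    GenotypeMatrix,
    Locus,
)

log = logging.getLogger(__name__)

_TIE_RTOL = 1e-10


@lru_cache(maxsize=100_000)
def _two_sided_by_a(m1: int, n: int, h: int) -> tuple[np.ndarray, int]:
    """Two-sided Fisher P for every achievable top-left cell count.

    Margins: row totals (m1, n - m1), column totals (h, n - h). Returns
    (p, a_min) where ``p[a - a_min]`` is the two-sided P of the table with
    top-left cell ``a``.
    """
    a_min = max(0, h - (n - m1))
    a_max = min(m1, h)
    support = np.arange(a_min, a_max + 1)
    pmf = stats.hypergeom.pmf(support, n, m1, h)
    # sum of point masses <= observed mass, with tolerance for exact ties
    p = np.array(
        [pmf[pmf <= pobs * (1 + _TIE_RTOL)].sum() for pobs in pmf]
    )
    return np.minimum(p, 1.0), a_min


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Two-sided Fisher exact P-value for a 2x2 table of counts."""
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise PreconditionError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise PreconditionError("table entries must be integers")
        t = t.astype(int)
    if np.any(t < 0):
        raise PreconditionError(f"negative count in table {t.tolist()}")
    n = int(t.sum())
    if n == 0:
        raise PreconditionError("table has no observations (all margins zero)")
    m1 = int(t[0].sum())
    h = int(t[:, 0].sum())
    p, a_min = _two_sided_by_a(m1, n, h)
    return float(p[int(t[0, 0]) - a_min])


def fisher_two_sided_from_margins(
    a: np.ndarray, m1: np.ndarray, n: np.ndarray, h: np.ndarray
) -> np.ndarray:
    """Vectorized two-sided Fisher P for tables given by margins + one cell.

    All arguments broadcast to a common shape; margins are grouped so each
    distinct (m1, n, h) triple is solved once.
    """
    a, m1, n, h = np.broadcast_arrays(a, m1, n, h)
    out = np.empty(a.shape, dtype=float)
    flat_a = a.ravel()
    flat_out = out.ravel()
    keys = np.stack([m1.ravel(), n.ravel(), h.ravel()], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    for g, (m1_g, n_g, h_g) in enumerate(uniq):
        p, a_min = _two_sided_by_a(int(m1_g), int(n_g), int(h_g))
        mask = inverse == g
        flat_out[mask] = p[flat_a[mask] - a_min]
    return out


def contingency_table(
    calls: np.ndarray,
    strains: Sequence[str],
    phenotype: BinaryPhenotype,
    alleles: tuple[str, str],
) -> np.ndarray:
    """2x2 counts of allele (rows, in ``alleles`` order) x high/low (cols).

    Strains with a missing call, or absent from the phenotype, are excluded
    from this locus's table only.
    """
    calls = np.asarray(calls, dtype="<U1")
    counts = np.zeros((2, 2), dtype=int)
    shared = 0
    for strain, call in zip(strains, calls):
        if call == MISSING:
            continue
        b = phenotype.bins.get(strain)
        if b is None:
            continue
        shared += 1
        counts[alleles.index(call), 0 if b == HIGH else 1] += 1
    if shared == 0:
        raise PreconditionError("no strains shared between genotype calls and phenotype")
    return counts


def _high_allele(counts: np.ndarray, alleles: tuple[str, str]) -> str | None:
    h = counts[:, 0].sum()
    l = counts[:, 1].sum()
    if h == 0 or l == 0:
        return None
    diff = counts[0, 0] / h - counts[0, 1] / l
    if diff > 0:
        return alleles[0]
    if diff < 0:
        return alleles[1]
    return None


def associate_locus(
    locus: Locus,
    calls: np.ndarray,
    strains: Sequence[str],
    phenotype: BinaryPhenotype,
) -> AssociationRecord:
    """Fisher exact association of one bi-allelic locus with the phenotype."""
    if not locus.is_biallelic:
        raise PreconditionError(f"locus {locus.id} is not bi-allelic")
    alleles = (locus.alleles[0], locus.alleles[1])
    counts = contingency_table(calls, strains, phenotype, alleles)
    p = fisher_exact(counts)
    return AssociationRecord(
        locus=locus,
        counts=counts,
        p_nominal=p,
        neg_log10_p=float(-np.log10(p)),
        high_allele=_high_allele(counts, alleles),
    )


def run_gwas(
    G: GenotypeMatrix, phenotype: BinaryPhenotype
) -> list[AssociationRecord]:
    """Test every curated locus, in input order, against the binary phenotype."""
    if G.n_loci == 0:
        log.warning("run_gwas called with an empty locus set")
        return []
    return [
        associate_locus(locus, G.calls[:, j], G.strains, phenotype)
        for j, locus in enumerate(G.loci)
    ]


def manhattan_table(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Plot-ready table sorted by genomic coordinate.

    Columns: linkage_group, position, locus_id, p, neg_log10_p, high_allele.
    """
    if not records:
        raise PreconditionError("manhattan_table requires at least one record")
    df = pd.DataFrame(
        {
            "linkage_group": [r.locus.linkage_group for r in records],
            "position": [r.locus.position for r in records],
            "locus_id": [r.locus.id for r in records],
            "p": [r.p_nominal for r in records],
            "neg_log10_p": [r.neg_log10_p for r in records],
            "high_allele": [r.high_allele or "." for r in records],
        }
    )
    return df.sort_values(["linkage_group", "position"], kind="mergesort").reset_index(
        drop=True
    )
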