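"""Permutation min-P family-wise significance for the forward GWAS.

The empirical null is built by shuffling the high/low phenotype labels across
strains (preserving the high/low counts), retesting every locus, and keeping
the minimum nominal P-value of each permutation. Two uses are exposed:

* the literal removal rule — any nominal P-value larger than the smallest
  permuted minimum is removed; equality survives. With B permutations the
  observed labelling is one of B + 1 exchangeable labellings, so under a
  complete null at most a 1/(B+1) fraction of datasets retains any locus.
* conventional Westfall-Young adjusted P-values,
  adj(p) = (1 + #{b : min_p[b] <= p}) / (B + 1), monotone in p.
"""

from __future__ import annotations

import numpy as np

from .association import fisher_two_sided_from_margins
from .errors import PreconditionError
from .types import (
    HIGH,
    MISSING,
    AssociationRecord,
    BinaryPhenotype,
    GenotypeMatrix,
    Locus,
    PermutationResult,
)


def _permutation_arrays(G: GenotypeMatrix, phenotype: BinaryPhenotype):
    """Boolean minor-allele / called indicators restricted to binned strains."""
    shared_idx = [i for i, s in enumerate(G.strains) if s in phenotype.bins]
    if not shared_idx:
        raise PreconditionError("no strains shared between genotypes and phenotype")
    for locus in G.loci:
        if not locus.is_biallelic:
            raise PreconditionError(
                f"locus {locus.id} is not bi-allelic; curate the matrix first"
            )
    calls = G.calls[shared_idx, :]
    minor = np.array([l.minor for l in G.loci], dtype="<U1")
    called = calls != MISSING
    minor_called = (calls == minor[None, :]) & called
    h = np.array(
        [phenotype.bins[G.strains[i]] == HIGH for i in shared_idx], dtype=float
    )
    return minor_called.astype(float), called.astype(float), h


def min_p_for_labels(
    minor_called: np.ndarray, called: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Minimum two-sided Fisher P across loci for each labelling row.

    ``labels`` has shape (B, n_strains) of 0/1 high indicators; the result
    has shape (B,).
    """
    a = labels @ minor_called           # minor-allele strains binned high
    h = labels @ called                 # high strains with a call
    m1 = minor_called.sum(axis=0)       # minor-allele strains with a call
    n = called.sum(axis=0)              # strains with a call
    p = fisher_two_sided_from_margins(
        np.rint(a).astype(int),
        np.rint(m1).astype(int)[None, :],
        np.rint(n).astype(int)[None, :],
        np.rint(h).astype(int),
    )
    return p.min(axis=1)


def permutation_min_p(
    G: GenotypeMatrix, phenotype: BinaryPhenotype, b: int, seed: int
) -> PermutationResult:
    """Empirical null of minimum P-values over ``b`` label shuffles.

    Fully reproducible: a single integer seed drives the whole permutation
    stream. Label arrangements are drawn uniformly (collisions between
    permutations are not excluded; with B far below the number of possible
    arrangements they are negligible).
    """
    if b < 1:
        raise PreconditionError(f"number of permutations must be >= 1, got {b}")
    minor_called, called, h = _permutation_arrays(G, phenotype)
    rng = np.random.default_rng(seed)
    labels = np.array([rng.permutation(h) for _ in range(b)])
    min_p = min_p_for_labels(minor_called, called, labels)
    return PermutationResult(b=b, min_p=min_p, seed=seed)


def literal_cutoff_filter(
    records: list[AssociationRecord], perm: PermutationResult
) -> list[AssociationRecord]:
    """Keep records whose nominal P is at or below the smallest permuted
    minimum (the removal rule drops only P-values strictly larger)."""
    return [r for r in records if r.p_nominal <= perm.cutoff]


def westfall_young_adjust(
    records: list[AssociationRecord], perm: PermutationResult
) -> dict[str, float]:
    """Westfall-Young adjusted P per locus id: (1 + #{min_p <= p}) / (B + 1)."""
    min_p = np.sort(perm.min_p)
    out = {}
    for r in records:
        count = int(np.searchsorted(min_p, r.p_nominal, side="right"))
        out[r.locus.id] = (1 + count) / (perm.b + 1)
    return out


def write_permutation_null(perm: PermutationResult, path) -> None:
    """Dump the permutation null, one minimum P per row."""
    from .io_formats import format_p

    with open(path, "w") as fh:
        fh.write("min_p\n")
        for p in perm.min_p:
            fh.write(format_p(p) + "\n")
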