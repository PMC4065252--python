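"""Core data containers for haploid association analyses.

The population under study is haploid (one allele per strain per site), so a
genotype is a single nucleotide character and genotype matrices are plain
strain x locus character arrays. Expression is stored as RPKM (reads per
kilobase of transcript per million mapped reads), non-negative by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import DegenerateDataError, ValidationError

VALID_ALLELES = frozenset("ACGT")
MISSING = "."

N_LINKAGE_GROUPS = 7

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7}
_TO_ROMAN = {v: k for k, v in _ROMAN.items()}


def parse_linkage_group(value) -> int:
    """Parse a linkage-group label (integer 1-7 or roman numeral I-VII)."""
    text = str(value).strip()
    upper = text.upper()
    if upper in _ROMAN:
        return _ROMAN[upper]
    try:
        lg = int(text)
    except ValueError:
        raise ValidationError(
            f"linkage group {text!r} is neither an integer 1-7 nor a roman numeral I-VII"
        ) from None
    if not 1 <= lg <= N_LINKAGE_GROUPS:
        raise ValidationError(f"linkage group {lg} outside 1..{N_LINKAGE_GROUPS}")
    return lg


def linkage_group_roman(lg: int) -> str:
    """Roman-numeral label for a linkage group (1 -> 'I')."""
    return _TO_ROMAN[lg]


@dataclass(frozen=True)
class Locus:
    """A bi-allelic SNP site on one of the seven linkage groups.

    ``alleles`` lists the observed alleles ordered by descending population
    count (ties broken alphabetically); for a curated bi-allelic locus this is
    the (major, minor) pair.
    """

    id: str
    linkage_group: int
    position: int
    alleles: tuple[str, ...]

    def __post_init__(self):
        if not self.id:
            raise ValidationError("locus id must be non-empty")
        if not 1 <= self.linkage_group <= N_LINKAGE_GROUPS:
            raise ValidationError(
                f"locus {self.id}: linkage group {self.linkage_group} outside 1..{N_LINKAGE_GROUPS}"
            )
        if self.position < 1:
            raise ValidationError(
                f"locus {self.id}: position {self.position} must be >= 1 (1-based)"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise ValidationError(f"locus {self.id}: duplicate alleles {self.alleles}")
        bad = set(self.alleles) - VALID_ALLELES
        if bad:
            raise ValidationError(f"locus {self.id}: invalid alleles {sorted(bad)}")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alleles) == 2

    @property
    def major(self) -> str:
        if not self.is_biallelic:
            raise DegenerateDataError(f"locus {self.id} is not bi-allelic")
        return self.alleles[0]

    @property
    def minor(self) -> str:
        if not self.is_biallelic:
            raise DegenerateDataError(f"locus {self.id} is not bi-allelic")
        return self.alleles[1]


def observed_alleles(calls: np.ndarray) -> tuple[str, ...]:
    """Alleles observed in a call vector, ordered by (-count, character)."""
    vals, counts = np.unique(calls[calls != MISSING], return_counts=True)
    order = sorted(range(len(vals)), key=lambda i: (-counts[i], vals[i]))
    return tuple(str(vals[i]) for i in order)


@dataclass
class GenotypeMatrix:
    """Haploid allele calls for strains x loci.

    ``calls`` has shape (n_strains, n_loci) with single-character entries;
    ``"."`` marks a missing call and is never counted as an allele.
    """

    strains: list[str]
    loci: list[Locus]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype="<U1")
        self.validate()

    @classmethod
    def from_calls(
        cls,
        strains: Iterable[str],
        loci_meta: Iterable[tuple[str, int, int]],
        calls: np.ndarray,
    ) -> "GenotypeMatrix":
        """Build a matrix deriving each locus's allele pair from its calls.

        ``loci_meta`` yields (locus_id, linkage_group, position) triples.
        """
        calls = np.asarray(calls, dtype="<U1")
        loci = [
            Locus(lid, lg, pos, observed_alleles(calls[:, j]))
            for j, (lid, lg, pos) in enumerate(loci_meta)
        ]
        return cls(list(strains), loci, calls)

    def validate(self) -> None:
        if len(set(self.strains)) != len(self.strains):
            dup = _first_duplicate(self.strains)
            raise ValidationError(f"duplicate strain id {dup!r}")
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            dup = _first_duplicate(ids)
            raise ValidationError(f"duplicate locus id {dup!r}")
        if self.calls.shape != (len(self.strains), len(self.loci)):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.strains)}, {len(self.loci)})"
            )
        for j, locus in enumerate(self.loci):
            col = self.calls[:, j]
            present = set(col[col != MISSING].tolist())
            bad = present - set(locus.alleles)
            if bad:
                raise ValidationError(
                    f"locus {locus.id}: calls {sorted(bad)} not among "
                    f"declared alleles {locus.alleles}"
                )

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def strain_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.strains)}

    def locus_index(self) -> dict[str, int]:
        return {l.id: j for j, l in enumerate(self.loci)}

    def locus_calls(self, locus_id: str) -> np.ndarray:
        return self.calls[:, self.locus_index()[locus_id]]

    def subset_loci(self, keep: Iterable[int]) -> "GenotypeMatrix":
        idx = list(keep)
        return GenotypeMatrix(
            strains=list(self.strains),
            loci=[self.loci[j] for j in idx],
            calls=self.calls[:, idx].copy(),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.strains == other.strains
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class ExpressionMatrix:
    """RPKM expression values, genes x strains, all non-negative."""

    genes: list[str]
    strains: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"duplicate gene id {_first_duplicate(self.genes)!r}")
        if len(set(self.strains)) != len(self.strains):
            raise ValidationError(
                f"duplicate strain id {_first_duplicate(self.strains)!r}"
            )
        if self.values.shape != (len(self.genes), len(self.strains)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.genes)}, {len(self.strains)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression {self.values[g, s]} for gene "
                f"{self.genes[g]!r}, strain {self.strains[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.gene_index()[gene], :]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def value(self, gene: str, strain: str) -> float:
        i = self.gene_index()[gene]
        try:
            j = self.strains.index(strain)
        except ValueError:
            raise KeyError(f"strain {strain!r} not in expression matrix") from None
        return float(self.values[i, j])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.genes == other.genes
            and self.strains == other.strains
            and np.allclose(self.values, other.values, rtol=0, atol=0)
        )


HIGH = "high"
LOW = "low"


@dataclass
class BinaryPhenotype:
    """Strain -> {high, low} resistance proxy from focal-gene expression.

    ``mean_value`` is the population mean the split was made against; a strain
    is "high" iff its focal-gene RPKM strictly exceeds it.
    """

    focal_gene: str
    mean_value: float
    bins: dict[str, str]
    n_high: int = field(init=False)
    n_low: int = field(init=False)

    def __post_init__(self):
        bad = {b for b in self.bins.values() if b not in (HIGH, LOW)}
        if bad:
            raise ValidationError(f"invalid bin labels {sorted(bad)}")
        self.n_high = sum(1 for b in self.bins.values() if b == HIGH)
        self.n_low = len(self.bins) - self.n_high

    @property
    def strains(self) -> list[str]:
        return list(self.bins)

    def high_strains(self) -> list[str]:
        return [s for s, b in self.bins.items() if b == HIGH]

    def low_strains(self) -> list[str]:
        return [s for s, b in self.bins.items() if b == LOW]


@dataclass
class AssociationRecord:
    """Per-locus 2x2 allele x bin counts with the Fisher exact P-value.

    ``counts`` rows follow ``locus.alleles`` order, columns are (high, low).
    ``high_allele`` is the allele overrepresented among "high" strains, or
    None when both alleles have identical high/low proportions.
    """

    locus: Locus
    counts: np.ndarray
    p_nominal: float
    neg_log10_p: float
    high_allele: str | None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValidationError("counts must be 2x2")
        if not 0 < self.p_nominal <= 1:
            raise ValidationError(f"p_nominal {self.p_nominal} outside (0, 1]")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AssociationRecord)
            and self.locus == other.locus
            and np.array_equal(self.counts, other.counts)
            and self.p_nominal == other.p_nominal
            and self.neg_log10_p == other.neg_log10_p
            and self.high_allele == other.high_allele
        )


@dataclass
class PermutationResult:
    """Empirical null of per-permutation minimum P-values.

    ``cutoff`` is the smallest permuted minimum: the literal removal rule
    keeps only nominal P-values at or below it.
    """

    b: int
    min_p: np.ndarray
    seed: int
    cutoff: float = field(init=False)

    def __post_init__(self):
        self.min_p = np.asarray(self.min_p, dtype=float)
        if self.min_p.shape != (self.b,):
            raise ValidationError(f"min_p length {self.min_p.shape} != B={self.b}")
        if self.b > 0:
            if np.any(self.min_p <= 0) or np.any(self.min_p > 1):
                raise ValidationError("permuted minimum P-values outside (0, 1]")
            self.cutoff = float(self.min_p.min())
        else:
            self.cutoff = float("nan")


@dataclass
class EqtlRecord:
    """Genotype-vs-expression test result for one (locus, gene) pair."""

    locus: Locus
    gene: str
    n_per_genotype: tuple[int, int]
    u_statistic: float
    p_value: float
    higher_expression_allele: str | None

    def __post_init__(self):
        if min(self.n_per_genotype) < 1:
            raise ValidationError("both genotype groups must be non-empty")
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")


@dataclass
class EnrichmentRecord:
    """Hypergeometric over-representation result for one category."""

    category: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_bh: float | None = None

    def __post_init__(self):
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValidationError(
                f"inconsistent enrichment counts k={self.k} K={self.K} "
                f"n={self.n} N={self.N}"
            )
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")


def _first_duplicate(items: Iterable[str]) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
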