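"""SNP-set curation: bi-allelic retention and minor-allele-frequency filtering.

The curation mirrors the usual wild-population workflow: keep only sites with
exactly two observed alleles, then keep only sites whose minor allele is
present at strictly more than a threshold frequency (default 10%) among
non-missing calls. Missing calls never count as alleles.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, PreconditionError, ValidationError
from .types import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MafFilterConfig:
    """Minor-allele-frequency filter settings.

    ``threshold`` is a fraction in [0, 0.5]; comparison is strict-greater, so
    a site whose MAF equals the threshold exactly is removed, and a zero
    threshold is the vacuous filter keeping every polymorphic site.
    """

    threshold: float = 0.10

    def __post_init__(self):
        if not 0 <= self.threshold <= 0.5:
            raise ValidationError(f"MAF threshold {self.threshold} outside [0, 0.5]")


def allele_counts(calls: np.ndarray) -> dict[str, int]:
    """Count alleles at one locus over non-missing calls."""
    calls = np.asarray(calls, dtype="<U1")
    present = calls[calls != MISSING]
    if present.size == 0:
        raise DegenerateDataError("all calls missing at locus")
    return dict(Counter(present.tolist()))


def filter_biallelic(G: GenotypeMatrix) -> GenotypeMatrix:
    """Retain only loci with exactly two distinct non-missing alleles."""
    keep = [j for j, locus in enumerate(G.loci) if len(locus.alleles) == 2]
    removed = G.n_loci - len(keep)
    if removed:
        log.info("filter_biallelic removed=%d retained=%d", removed, len(keep))
    return G.subset_loci(keep)


def minor_allele_frequency(calls: np.ndarray) -> float:
    """MAF of a bi-allelic locus: min(count)/total over non-missing calls."""
    counts = allele_counts(calls)
    if len(counts) != 2:
        raise PreconditionError(
            f"minor_allele_frequency requires a bi-allelic locus, got alleles "
            f"{sorted(counts)}"
        )
    values = list(counts.values())
    return min(values) / sum(values)


def filter_maf(
    G: GenotypeMatrix, cfg: MafFilterConfig | float = MafFilterConfig()
) -> GenotypeMatrix:
    """Retain loci whose MAF is strictly greater than ``cfg.threshold``.

    Non-bi-allelic loci are removed first (the MAF of a site with one or
    three alleles is undefined here).
    """
    if isinstance(cfg, float):
        cfg = MafFilterConfig(threshold=cfg)
    G2 = filter_biallelic(G)
    keep = [
        j
        for j in range(G2.n_loci)
        if minor_allele_frequency(G2.calls[:, j]) > cfg.threshold
    ]
    log.info(
        "filter_maf threshold=%g before=%d after=%d removed=%d",
        cfg.threshold, G.n_loci, len(keep), G.n_loci - len(keep),
    )
    return G2.subset_loci(keep)
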