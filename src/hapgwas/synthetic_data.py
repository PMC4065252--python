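"""Synthetic haploid wild-population datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes: a
population of ~113 haploid strains genotyped at bi-allelic SNPs spread over
the seven linkage groups, a focal gene whose (log-normal) expression carries
planted trans-SNP effects, cis genes whose expression depends on their own
SNP, an optionally co-regulated partner gene, and independent log-normal
noise genes. Loci are unlinked and strains unstructured — deliberate
simplifications that make the error-rate arithmetic of the permutation
procedures exact.

Per locus a minor-allele frequency is drawn uniformly from ``maf_range``
(default 0.05-0.5, deliberately straddling the 0.10 curation threshold), and
each strain carries the minor allele independently with that probability.
Expression is Normal on the log2 scale (RPKM = 2^log2 value), with planted
additive effects in units of log2 expression per minor allele.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_formats import (
    read_expression_table,
    read_genotype_table,
    write_expression_table,
    write_genotype_table,
)
from .types import ExpressionMatrix, GenotypeMatrix

# approximate N. crassa chromosome lengths (bp), linkage groups I..VII
DEFAULT_LG_LENGTHS = (
    9_800_000, 4_500_000, 5_300_000, 6_000_000, 6_400_000, 4_200_000, 4_300_000
)

_ALLELE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic population.

    Defaults mirror the emulated study: 113 strains, seven linkage groups,
    log2-scale residual noise of 1.0, a baseline of 2^5 = 32 RPKM (the
    magnitude of a moderately expressed gene), planted trans effects of
    3 sigma and cis effects of 2 sigma. ``causal_maf``, when set, forces the
    minor-allele frequency of every planted (trans and cis) locus so planted
    effects are evaluated at a known allele balance.
    """

    n_strains: int = 113
    n_loci: int = 2000
    n_genes: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 1
    beta: float = 3.0
    n_cis: int = 3
    cis_beta: float = 2.0
    causal_maf: float | None = None
    partner_rho: float = 0.8
    sigma: float = 1.0
    baseline_log2: float = 5.0
    lg_lengths: tuple[int, ...] = DEFAULT_LG_LENGTHS
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if min(self.n_strains, self.n_loci, self.n_genes) < 1:
            raise ValidationError("n_strains, n_loci and n_genes must be >= 1")
        if self.n_causal < 0 or self.n_cis < 0:
            raise ValidationError("effect counts must be >= 0")
        if self.n_causal + self.n_cis > self.n_loci:
            raise ValidationError("n_causal + n_cis exceeds n_loci")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if not 0 <= self.partner_rho < 1:
            raise ValidationError("partner_rho must be in [0, 1)")
        if self.causal_maf is not None and not 0 < self.causal_maf <= 0.5:
            raise ValidationError("causal_maf outside (0, 0.5]")
        if len(self.lg_lengths) != 7:
            raise ValidationError("lg_lengths must list 7 linkage groups")
        n_special = 1 + (1 if self.partner_rho > 0 else 0) + self.n_cis
        if self.n_genes < n_special:
            raise ValidationError(
                f"n_genes={self.n_genes} too small for focal + partner + "
                f"{self.n_cis} cis genes"
            )


@dataclass(frozen=True)
class PlantedEffect:
    """One planted genotype->expression effect (trans or cis)."""

    locus_id: str
    gene: str
    beta: float
    effect_allele: str


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic dataset."""

    focal_gene: str
    causal: list[PlantedEffect] = field(default_factory=list)
    cis: list[PlantedEffect] = field(default_factory=list)
    partner_gene: str | None = None


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    truth: SimulationTruth
    config: SimulationConfig


FOCAL_GENE = "focal"
PARTNER_GENE = "partner"


def simulate_population(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset; reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    # --- loci ----------------------------------------------------------------
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, size=cfg.n_loci)
    planted = rng.choice(cfg.n_loci, size=cfg.n_causal + cfg.n_cis, replace=False)
    causal_idx = planted[: cfg.n_causal]
    cis_idx = planted[cfg.n_causal:]
    if cfg.causal_maf is not None:
        mafs[planted] = cfg.causal_maf
    lgs = rng.integers(1, 8, size=cfg.n_loci)
    positions = np.array(
        [rng.integers(1, cfg.lg_lengths[lg - 1] + 1) for lg in lgs]
    )
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=cfg.n_loci)
    width = len(str(cfg.n_loci))
    loci_meta = [
        (f"snp{j + 1:0{width}d}", int(lgs[j]), int(positions[j]))
        for j in range(cfg.n_loci)
    ]

    # haploid carriage: each strain carries the minor allele with prob MAF
    carries_minor = rng.random((cfg.n_strains, cfg.n_loci)) < mafs[None, :]
    calls = np.empty((cfg.n_strains, cfg.n_loci), dtype="<U1")
    for j in range(cfg.n_loci):
        major, minor = _ALLELE_PAIRS[pair_idx[j]]
        calls[:, j] = np.where(carries_minor[:, j], minor, major)

    strains = [f"strain{i + 1:03d}" for i in range(cfg.n_strains)]
    G = GenotypeMatrix.from_calls(strains, loci_meta, calls)

    # --- expression ----------------------------------------------------------
    truth = SimulationTruth(focal_gene=FOCAL_GENE)
    genes = [FOCAL_GENE]
    log2 = np.empty((cfg.n_genes, cfg.n_strains))

    focal = cfg.baseline_log2 + rng.normal(0, cfg.sigma, cfg.n_strains)
    for j in causal_idx:
        focal = focal + cfg.beta * carries_minor[:, j]
        truth.causal.append(
            PlantedEffect(
                locus_id=loci_meta[j][0],
                gene=FOCAL_GENE,
                beta=cfg.beta,
                effect_allele=_ALLELE_PAIRS[pair_idx[j]][1],
            )
        )
    log2[0, :] = focal

    row = 1
    if cfg.partner_rho > 0:
        # scale the focal signal so the log2-scale Pearson correlation with
        # the partner is approximately partner_rho
        sd_f = float(focal.std())
        a = cfg.partner_rho * cfg.sigma / (sd_f * np.sqrt(1 - cfg.partner_rho**2))
        log2[row, :] = (
            cfg.baseline_log2
            + a * (focal - focal.mean())
            + rng.normal(0, cfg.sigma, cfg.n_strains)
        )
        genes.append(PARTNER_GENE)
        truth.partner_gene = PARTNER_GENE
        row += 1

    for i, j in enumerate(cis_idx):
        gene = f"cis_g{i + 1:03d}"
        log2[row, :] = (
            cfg.baseline_log2
            + cfg.cis_beta * carries_minor[:, j]
            + rng.normal(0, cfg.sigma, cfg.n_strains)
        )
        truth.cis.append(
            PlantedEffect(
                locus_id=loci_meta[j][0],
                gene=gene,
                beta=cfg.cis_beta,
                effect_allele=_ALLELE_PAIRS[pair_idx[j]][1],
            )
        )
        genes.append(gene)
        row += 1

    n_null = cfg.n_genes - row
    log2[row:, :] = cfg.baseline_log2 + rng.normal(
        0, cfg.sigma, (n_null, cfg.n_strains)
    )
    genes.extend(f"gene{i + 1:04d}" for i in range(n_null))

    expr = ExpressionMatrix(genes=genes, strains=strains, values=2.0 ** log2)
    return SyntheticDataset(genotypes=G, expression=expr, truth=truth, config=cfg)


def simulate_null(cfg: SimulationConfig) -> SyntheticDataset:
    """A dataset with no planted effects: expression independent of genotype."""
    null_cfg = dataclasses.replace(cfg, n_causal=0, n_cis=0, partner_rho=0.0)
    return simulate_population(null_cfg)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

_TRUTH_COLS = ["kind", "locus_id", "gene", "beta", "effect_allele"]


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write genotypes.tsv, expression.tsv and truth.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotype_table(ds.genotypes, outdir / "genotypes.tsv")
    write_expression_table(ds.expression, outdir / "expression.tsv")
    with (outdir / "truth.tsv").open("w") as fh:
        fh.write("\t".join(_TRUTH_COLS) + "\n")
        for eff in ds.truth.causal:
            fh.write(
                f"trans\t{eff.locus_id}\t{eff.gene}\t{eff.beta!r}\t{eff.effect_allele}\n"
            )
        for eff in ds.truth.cis:
            fh.write(
                f"cis\t{eff.locus_id}\t{eff.gene}\t{eff.beta!r}\t{eff.effect_allele}\n"
            )
        if ds.truth.partner_gene is not None:
            fh.write(f"partner\t.\t{ds.truth.partner_gene}\t.\t.\n")


def read_dataset(outdir) -> tuple[GenotypeMatrix, ExpressionMatrix, SimulationTruth]:
    """Read back a written dataset (matrices plus ground truth)."""
    outdir = Path(outdir)
    G = read_genotype_table(outdir / "genotypes.tsv")
    expr = read_expression_table(outdir / "expression.tsv")
    truth = SimulationTruth(focal_gene=FOCAL_GENE)
    with (outdir / "truth.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLS:
            raise ValidationError(f"unexpected truth.tsv columns {header}")
        for line in fh:
            kind, locus_id, gene, beta, allele = line.rstrip("\n").split("\t")
            if kind == "partner":
                truth.partner_gene = gene
                continue
            eff = PlantedEffect(
                locus_id=locus_id, gene=gene, beta=float(beta), effect_allele=allele
            )
            (truth.causal if kind == "trans" else truth.cis).append(eff)
    return G, expr, truth
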