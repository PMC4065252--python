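"""Plain-text readers and writers for all pipeline tables.

Formats (all tab-separated, UTF-8, one header row):

* genotype table:   ``locus_id  linkage_group  position  <strain1> ... <strainN>``
  with one row per locus; calls are single characters A/C/G/T and ``.`` for a
  missing call. Linkage groups may be integers 1-7 or roman numerals I-VII.
* expression table: ``gene_id  <strain1> ... <strainN>`` with RPKM values.
* annotation table: ``gene_id  category`` (one row per membership).
* phenotype table:  ``strain  bin  value`` preceded by a ``#focal_gene=...``
  comment carrying the split metadata.
* result tables:    fixed column orders per record type (see writers below);
  P-values are serialised in scientific notation with enough digits to
  round-trip the exact floating-point value.

A minimal haploid VCF reader (via pysam) is provided for genotype input;
diploid GT fields are rejected, since the organism is haploid.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, PloidyError, ValidationError
from .types import (
    MISSING,
    VALID_ALLELES,
    AssociationRecord,
    BinaryPhenotype,
    EnrichmentRecord,
    EqtlRecord,
    ExpressionMatrix,
    GenotypeMatrix,
    Locus,
    parse_linkage_group,
)

_NA = "."


def format_p(p: float) -> str:
    """Scientific-notation P-value with >=3 significant digits.

    Uses the shortest representation that round-trips the exact double, so
    written tables read back bit-identically (e.g. 3.44e-07 -> "3.44E-07").
    """
    return np.format_float_scientific(
        float(p), unique=True, min_digits=2, exp_digits=2
    ).upper()


def _format_float(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def read_genotype_table(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``path``.

    ``dialect`` is ``"tsv"`` (the canonical interchange format) or
    ``"vcf-haploid"`` (read-only VCF restricted to single-allele GT records).
    """
    if dialect == "tsv":
        return _read_genotype_tsv(path)
    if dialect == "vcf-haploid":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_tsv_with_raw_header(path: Path) -> tuple[list[str], pd.DataFrame]:
    """Read a TSV keeping the header verbatim (pandas silently renames
    duplicate column labels, which would hide duplicate strain ids)."""
    with path.open() as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}: empty table")
        columns = header_line.split("\t")
        df = pd.read_csv(
            fh, sep="\t", dtype=str, keep_default_na=False, header=None,
            names=range(len(columns)),
        )
    if df.shape[1] != len(columns) and len(df):
        raise FormatError(f"{path}: ragged rows (header has {len(columns)} columns)")
    return columns, df


def _read_genotype_tsv(path) -> GenotypeMatrix:
    path = Path(path)
    columns, df = _read_tsv_with_raw_header(path)
    df.columns = [f"c{i}" for i in range(len(columns))]
    required = ["locus_id", "linkage_group", "position"]
    if columns[:3] != required:
        raise FormatError(
            f"{path}: first three columns must be {required}, got {columns[:3]}"
        )
    df = df.rename(columns={"c0": "locus_id", "c1": "linkage_group", "c2": "position"})
    strains = columns[3:]
    if not strains:
        raise FormatError(f"{path}: no strain columns")
    dup = _first_dup(strains)
    if dup is not None:
        raise FormatError(f"{path}: duplicate strain id {dup!r} in header")
    dup = _first_dup(df["locus_id"].tolist())
    if dup is not None:
        raise FormatError(f"{path}: duplicate locus id {dup!r}")

    loci_meta = []
    for row_i, row in enumerate(df.itertuples(index=False)):
        try:
            lg = parse_linkage_group(row.linkage_group)
            pos = int(row.position)
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path}: row {row_i + 2}: {exc}") from None
        loci_meta.append((row.locus_id, lg, pos))

    call_cols = [f"c{i}" for i in range(3, len(columns))]
    calls = df[call_cols].to_numpy(dtype="<U1").T  # strains x loci
    raw = df[call_cols].to_numpy(dtype=str).T
    ok = np.isin(raw, sorted(VALID_ALLELES) + [MISSING])
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise FormatError(
            f"{path}: invalid call {raw[i, j]!r} at locus {loci_meta[j][0]!r}, "
            f"strain {strains[i]!r} (row {j + 2}, column {i + 4})"
        )
    try:
        return GenotypeMatrix.from_calls(strains, loci_meta, calls)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def _read_genotype_vcf(path) -> GenotypeMatrix:
    import pysam

    path = Path(path)
    with pysam.VariantFile(str(path)) as vcf:
        strains = list(vcf.header.samples)
        dup = _first_dup(strains)
        if dup is not None:
            raise FormatError(f"{path}: duplicate sample id {dup!r}")
        loci_meta = []
        columns = []
        for rec in vcf:
            alleles = [rec.ref, *(rec.alts or ())]
            if any(a is None or len(a) != 1 or a not in VALID_ALLELES for a in alleles):
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not a simple SNP"
                )
            col = []
            for s in strains:
                gt = rec.samples[s].get("GT", (None,))
                if len(gt) != 1:
                    raise PloidyError(
                        f"{path}: record {rec.chrom}:{rec.pos}, sample {s!r}: "
                        f"GT has ploidy {len(gt)}; only haploid calls are supported"
                    )
                col.append(MISSING if gt[0] is None else alleles[gt[0]])
            lid = rec.id or f"{rec.chrom}_{rec.pos}"
            loci_meta.append((lid, parse_linkage_group(rec.chrom), rec.pos))
            columns.append(col)
    if not loci_meta:
        raise FormatError(f"{path}: VCF contains no records")
    calls = np.array(columns, dtype="<U1").T
    dup = _first_dup([m[0] for m in loci_meta])
    if dup is not None:
        raise FormatError(f"{path}: duplicate locus id {dup!r}")
    return GenotypeMatrix.from_calls(strains, loci_meta, calls)


def write_genotype_table(G: GenotypeMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["locus_id", "linkage_group", "position", *G.strains]))
        fh.write("\n")
        for j, locus in enumerate(G.loci):
            row = [locus.id, str(locus.linkage_group), str(locus.position)]
            row.extend(G.calls[:, j].tolist())
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path) -> ExpressionMatrix:
    path = Path(path)
    columns, df = _read_tsv_with_raw_header(path)
    if columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {columns[0]!r}")
    strains = columns[1:]
    if not strains:
        raise FormatError(f"{path}: no strain columns")
    genes = df[0].tolist()
    raw = df[list(range(1, len(columns)))].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(raw):
        try:
            values[i, j] = float(cell)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: non-numeric value {cell!r} for gene {genes[i]!r}, "
                f"strain {strains[j]!r}"
            ) from None
    try:
        return ExpressionMatrix(genes=genes, strains=strains, values=values)
    except ValidationError:
        raise


def write_expression_table(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["gene_id", *expr.strains]) + "\n")
        for i, gene in enumerate(expr.genes):
            row = [gene] + [_format_float(v) for v in expr.values[i, :]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_annotation_table(path) -> dict[str, set[str]]:
    """Read a gene -> categories map (one ``gene_id<TAB>category`` row per
    membership; a gene may appear under several categories)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["gene_id", "category"]:
        raise FormatError(
            f"{path}: expected columns ['gene_id', 'category'], got {list(df.columns[:2])}"
        )
    annotation: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        annotation.setdefault(row.gene_id, set()).add(row.category)
    return annotation


def write_annotation_table(annotation: Mapping[str, set[str]], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\tcategory\n")
        for gene in annotation:
            for cat in sorted(annotation[gene]):
                fh.write(f"{gene}\t{cat}\n")


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def write_phenotype_table(
    phen: BinaryPhenotype, path, values: Mapping[str, float] | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"#focal_gene={phen.focal_gene}\tmean_value={_format_float(phen.mean_value)}\n"
        )
        fh.write("strain\tbin\tvalue\n")
        for strain, b in phen.bins.items():
            val = _NA if values is None else _format_float(values[strain])
            fh.write(f"{strain}\t{b}\t{val}\n")


def read_phenotype_table(path) -> BinaryPhenotype:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#focal_gene="):
            raise FormatError(f"{path}: missing '#focal_gene=' metadata line")
        meta = dict(field.split("=", 1) for field in header[1:].split("\t"))
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["strain", "bin"]:
        raise FormatError(f"{path}: expected columns ['strain', 'bin', 'value']")
    bins = dict(zip(df["strain"], df["bin"]))
    if len(bins) != len(df):
        raise FormatError(f"{path}: duplicate strain in phenotype table")
    return BinaryPhenotype(
        focal_gene=meta["focal_gene"],
        mean_value=float(meta["mean_value"]),
        bins=bins,
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_ASSOC_COLS = [
    "linkage_group", "position", "locus_id", "allele1", "allele2",
    "a1_high", "a1_low", "a2_high", "a2_low", "p", "neg_log10_p", "high_allele",
]
_EQTL_COLS = [
    "linkage_group", "position", "locus_id", "allele1", "allele2", "gene",
    "n_allele1", "n_allele2", "u", "p", "higher_expression_allele",
]
_ENRICH_COLS = ["category", "k", "K", "n", "N", "p", "p_bh"]


def write_results(records: Sequence, path, kind: str | None = None) -> None:
    """Write association, eQTL, or enrichment records as a TSV table.

    ``kind`` ("association", "eqtl", "enrichment") is inferred from the first
    record; it must be given explicitly for an empty list (header-only file).
    """
    if records:
        kind = {
            AssociationRecord: "association",
            EqtlRecord: "eqtl",
            EnrichmentRecord: "enrichment",
        }[type(records[0])]
    elif kind is None:
        raise ValidationError("kind is required to write an empty result table")
    writer = {
        "association": _write_association,
        "eqtl": _write_eqtl,
        "enrichment": _write_enrichment,
    }[kind]
    writer(records, Path(path))


def _write_association(records, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(_ASSOC_COLS) + "\n")
        for r in records:
            l = r.locus
            fh.write(
                "\t".join(
                    [
                        str(l.linkage_group), str(l.position), l.id,
                        l.alleles[0], l.alleles[1],
                        str(r.counts[0, 0]), str(r.counts[0, 1]),
                        str(r.counts[1, 0]), str(r.counts[1, 1]),
                        format_p(r.p_nominal), _format_float(r.neg_log10_p),
                        r.high_allele or _NA,
                    ]
                )
                + "\n"
            )


def read_association_table(path) -> list[AssociationRecord]:
    df = _read_result_frame(path, _ASSOC_COLS)
    records = []
    for row in df.itertuples(index=False):
        locus = Locus(
            id=row.locus_id,
            linkage_group=parse_linkage_group(row.linkage_group),
            position=int(row.position),
            alleles=(row.allele1, row.allele2),
        )
        records.append(
            AssociationRecord(
                locus=locus,
                counts=np.array(
                    [[int(row.a1_high), int(row.a1_low)],
                     [int(row.a2_high), int(row.a2_low)]]
                ),
                p_nominal=float(row.p),
                neg_log10_p=float(row.neg_log10_p),
                high_allele=None if row.high_allele == _NA else row.high_allele,
            )
        )
    return records


def _write_eqtl(records, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(_EQTL_COLS) + "\n")
        for r in records:
            l = r.locus
            fh.write(
                "\t".join(
                    [
                        str(l.linkage_group), str(l.position), l.id,
                        l.alleles[0], l.alleles[1], r.gene,
                        str(r.n_per_genotype[0]), str(r.n_per_genotype[1]),
                        _format_float(r.u_statistic), format_p(r.p_value),
                        r.higher_expression_allele or _NA,
                    ]
                )
                + "\n"
            )


def read_eqtl_table(path) -> list[EqtlRecord]:
    df = _read_result_frame(path, _EQTL_COLS)
    records = []
    for row in df.itertuples(index=False):
        locus = Locus(
            id=row.locus_id,
            linkage_group=parse_linkage_group(row.linkage_group),
            position=int(row.position),
            alleles=(row.allele1, row.allele2),
        )
        records.append(
            EqtlRecord(
                locus=locus,
                gene=row.gene,
                n_per_genotype=(int(row.n_allele1), int(row.n_allele2)),
                u_statistic=float(row.u),
                p_value=float(row.p),
                higher_expression_allele=(
                    None
                    if row.higher_expression_allele == _NA
                    else row.higher_expression_allele
                ),
            )
        )
    return records


def _write_enrichment(records, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(_ENRICH_COLS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.category, str(r.k), str(r.K), str(r.n), str(r.N),
                        format_p(r.p_value),
                        _NA if r.p_bh is None else format_p(r.p_bh),
                    ]
                )
                + "\n"
            )


def read_enrichment_table(path) -> list[EnrichmentRecord]:
    df = _read_result_frame(path, _ENRICH_COLS)
    return [
        EnrichmentRecord(
            category=row.category,
            k=int(row.k),
            K=int(row.K),
            n=int(row.n),
            N=int(row.N),
            p_value=float(row.p),
            p_bh=None if row.p_bh == _NA else float(row.p_bh),
        )
        for row in df.itertuples(index=False)
    ]


def _read_result_frame(path, expected_cols) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != expected_cols:
        raise FormatError(
            f"{path}: expected columns {expected_cols}, got {list(df.columns)}"
        )
    return df


def _first_dup(items) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
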