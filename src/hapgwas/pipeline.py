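"""End-to-end orchestration: filter -> bin -> GWAS -> permutation
significance -> reverse eQTL -> correlation -> enrichment.

Every stage writes its table under the output directory, a line-oriented
``run.log`` records input checksums, the seed and the stage counts, and the
whole run is deterministic given the config and seed (no timestamps). On a
stage failure a ``MANIFEST.partial`` file lists whatever was already
written, and the error names the failing stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import association, enrichment, eqtl_correlation, permutation_fwer
from .errors import HapgwasError, ValidationError
from .io_formats import (
    format_p,
    read_annotation_table,
    read_expression_table,
    read_genotype_table,
    write_genotype_table,
    write_phenotype_table,
    write_results,
)
from .phenotype_binning import bin_by_mean
from .variant_filtering import MafFilterConfig, filter_maf


class PipelineError(HapgwasError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One config drives all subcommands; ``run`` composes them."""

    genotypes: Path
    expression: Path
    focal_gene: str
    outdir: Path
    maf_threshold: float = 0.10
    permutations: int = 1000
    seed: int = 17
    annotation: Path | None = None
    reverse_loci: list[str] = field(default_factory=list)
    correlate: list[tuple[str, str]] = field(default_factory=list)
    enrichment_query: Path | None = None

    def __post_init__(self):
        if not self.focal_gene:
            raise ValidationError("focal_gene must be non-empty")
        if self.permutations < 0:
            raise ValidationError("permutations must be >= 0")
        self.genotypes = Path(self.genotypes)
        self.expression = Path(self.expression)
        self.outdir = Path(self.outdir)
        if self.annotation is not None:
            self.annotation = Path(self.annotation)
        if self.enrichment_query is not None:
            self.enrichment_query = Path(self.enrichment_query)


def load_pipeline_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; relative paths resolve against the file."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent
    for key in ("genotypes", "expression", "annotation", "enrichment_query", "outdir"):
        if raw.get(key) is not None:
            raw[key] = base / raw[key]
    if "correlate" in raw:
        raw["correlate"] = [tuple(pair) for pair in raw["correlate"]]
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns a name -> path map of written outputs."""
    outputs: dict[str, Path] = {}
    log_lines: list[str] = []

    def emit(message: str, **kv):
        suffix = " ".join(f"{k}={v}" for k, v in kv.items())
        log_lines.append(f"{message} {suffix}".strip())

    def finish_log():
        log_path = cfg.outdir / "run.log"
        log_path.write_text("\n".join(log_lines) + "\n")
        outputs["run_log"] = log_path

    stage = "validate-inputs"
    try:
        required = [cfg.expression, cfg.genotypes]
        if cfg.annotation is not None:
            required.append(cfg.annotation)
        if cfg.enrichment_query is not None:
            required.append(cfg.enrichment_query)
        for p in required:
            if not p.is_file():
                raise ValidationError(f"input file not found: {p}")
        cfg.outdir.mkdir(parents=True, exist_ok=True)
        for p in required:
            emit("input", path=p.name, sha256=_sha256(p))
        emit("config", seed=cfg.seed, maf_threshold=cfg.maf_threshold,
             permutations=cfg.permutations, focal_gene=cfg.focal_gene)

        stage = "read-expression"
        expr = read_expression_table(cfg.expression)
        emit("expression", genes=expr.n_genes, strains=expr.n_strains)

        stage = "read-genotypes"
        G = read_genotype_table(cfg.genotypes)
        emit("genotypes", strains=G.n_strains, loci=G.n_loci)

        stage = "filter"
        G_f = filter_maf(G, MafFilterConfig(threshold=cfg.maf_threshold))
        emit("filter", loci_before=G.n_loci, loci_after=G_f.n_loci,
             removed=G.n_loci - G_f.n_loci)
        path = cfg.outdir / "genotypes_filtered.tsv"
        write_genotype_table(G_f, path)
        outputs["genotypes_filtered"] = path

        stage = "bin"
        phen = bin_by_mean(expr, cfg.focal_gene)
        emit("bin", focal_gene=cfg.focal_gene, mean=phen.mean_value,
             n_high=phen.n_high, n_low=phen.n_low)
        values = dict(zip(expr.strains, expr.row(cfg.focal_gene)))
        path = cfg.outdir / "phenotype.tsv"
        write_phenotype_table(phen, path, values=values)
        outputs["phenotype"] = path

        stage = "gwas"
        records = association.run_gwas(G_f, phen)
        emit("gwas", records=len(records))
        path = cfg.outdir / "association.tsv"
        write_results(records, path, kind="association")
        outputs["association"] = path

        stage = "permutation"
        survivors = []
        if cfg.permutations >= 1 and records:
            perm = permutation_fwer.permutation_min_p(
                G_f, phen, cfg.permutations, cfg.seed
            )
            survivors = permutation_fwer.literal_cutoff_filter(records, perm)
            adjusted = permutation_fwer.westfall_young_adjust(records, perm)
            path = cfg.outdir / "permutation_null.tsv"
            permutation_fwer.write_permutation_null(perm, path)
            outputs["permutation_null"] = path
            emit("permutation", b=perm.b, cutoff=format_p(perm.cutoff),
                 survivors=len(survivors))
            path = cfg.outdir / "manhattan.tsv"
            table = association.manhattan_table(records)
            table["significant_literal"] = [
                int(p <= perm.cutoff) for p in table["p"]
            ]
            table["p_adjusted_wy"] = [
                format_p(adjusted[lid]) for lid in table["locus_id"]
            ]
            table["p"] = table["p"].map(format_p)
            table.to_csv(path, sep="\t", index=False)
            outputs["manhattan"] = path
        path = cfg.outdir / "significant.tsv"
        write_results(survivors, path, kind="association")
        outputs["significant"] = path

        stage = "eqtl"
        locus_by_id = {l.id: l for l in G_f.loci}
        sig_eqtl_genes: set[str] = set()
        for locus_id in cfg.reverse_loci:
            if locus_id not in locus_by_id:
                raise ValidationError(
                    f"reverse-scan locus {locus_id!r} not in the filtered matrix"
                )
            eq_records, eq_perm = eqtl_correlation.reverse_gwas(
                locus_by_id[locus_id], G_f, expr, b=cfg.permutations, seed=cfg.seed
            )
            path = cfg.outdir / f"eqtl_{locus_id}.tsv"
            write_results(eq_records, path, kind="eqtl")
            outputs[f"eqtl_{locus_id}"] = path
            kv = {"locus": locus_id, "genes": len(eq_records)}
            if eq_perm is not None:
                sig = eqtl_correlation.significant_eqtl(eq_records, eq_perm)
                sig_eqtl_genes.update(r.gene for r in sig)
                kv.update(cutoff=format_p(eq_perm.cutoff), significant=len(sig))
            emit("eqtl", **kv)

        stage = "correlate"
        if cfg.correlate:
            path = cfg.outdir / "correlation.tsv"
            with path.open("w") as fh:
                fh.write("gene_a\tgene_b\tspearman_rho\tp\n")
                for ga, gb in cfg.correlate:
                    rho, p = eqtl_correlation.expression_correlation(expr, ga, gb)
                    fh.write(f"{ga}\t{gb}\t{rho!r}\t{format_p(p)}\n")
                    emit("correlate", gene_a=ga, gene_b=gb, rho=round(rho, 4))
            outputs["correlation"] = path

        stage = "enrich"
        if cfg.annotation is not None:
            annotation = read_annotation_table(cfg.annotation)
            if cfg.enrichment_query is not None:
                query = [
                    line.strip()
                    for line in cfg.enrichment_query.read_text().splitlines()
                    if line.strip()
                ]
            else:
                # default query: genes significant in the reverse eQTL scans
                query = sorted(sig_eqtl_genes)
            if query:
                enr = enrichment.category_enrichment(query, expr.genes, annotation)
                path = cfg.outdir / "enrichment.tsv"
                write_results(enr, path, kind="enrichment")
                outputs["enrichment"] = path
                emit("enrich", query=len(query), categories=len(enr))

        finish_log()
        return outputs
    except Exception as exc:
        manifest = cfg.outdir / "MANIFEST.partial"
        if cfg.outdir.is_dir():
            manifest.write_text(
                f"failed_stage\t{stage}\n"
                + "".join(f"{name}\t{p.name}\n" for name, p in outputs.items())
            )
        raise PipelineError(stage, exc) from exc
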