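import numpy as np
import pytest

from hapgwas.association import run_gwas
from hapgwas.errors import ValidationError
from hapgwas.phenotype_binning import bin_by_mean
from hapgwas.synthetic_data import (
    SimulationConfig,
    read_dataset,
    simulate_null,
    simulate_population,
    write_dataset,
)
from hapgwas.types import MISSING
from hapgwas.variant_filtering import filter_maf


class TestSimulatePopulation:
    def test_shapes_and_invariants(self):
        cfg = SimulationConfig(n_strains=113, n_loci=500, n_genes=200, seed=1)
        ds = simulate_population(cfg)
        assert ds.genotypes.calls.shape == (113, 500)
        assert ds.expression.values.shape == (200, 113)
        assert ds.genotypes.strains == ds.expression.strains
        ds.genotypes.validate()
        ds.expression.validate()
        assert not np.any(ds.genotypes.calls == MISSING)
        # truth refers to existing loci/genes
        locus_ids = {l.id for l in ds.genotypes.loci}
        genes = set(ds.expression.genes)
        for eff in ds.truth.causal + ds.truth.cis:
            assert eff.locus_id in locus_ids and eff.gene in genes
        assert ds.truth.partner_gene in genes

    def test_reproducible_from_seed(self):
        cfg = SimulationConfig(n_strains=50, n_loci=100, n_genes=30, seed=42)
        assert simulate_population(cfg).genotypes == simulate_population(cfg).genotypes

    def test_empirical_maf_tracks_drawn_maf(self):
        # with forced planted MAF the empirical frequency must be within
        # 3 binomial standard errors for nearly all loci
        cfg = SimulationConfig(
            n_strains=400, n_loci=300, n_genes=5, n_causal=1, n_cis=1,
            causal_maf=0.4, seed=7,
        )
        ds = simulate_population(cfg)
        planted = {e.locus_id for e in ds.truth.causal + ds.truth.cis}
        se = np.sqrt(0.4 * 0.6 / 400)
        for locus in ds.genotypes.loci:
            if locus.id not in planted:
                continue
            col = ds.genotypes.calls[:, ds.genotypes.locus_index()[locus.id]]
            freq = np.mean(col == locus.minor) if locus.is_biallelic else 0.0
            freq = min(freq, 1 - freq)
            assert abs(freq - 0.4) < 3 * se

    def test_maf_filter_retains_expected_fraction(self):
        # MAF drawn uniform on (0.05, 0.5): after the 0.10 filter the retained
        # fraction is about (0.5-0.1)/(0.5-0.05) = 0.889, finite-sample jitter aside
        cfg = SimulationConfig(n_strains=113, n_loci=2000, n_genes=5, n_causal=0,
                               n_cis=0, partner_rho=0.0, seed=13)
        ds = simulate_population(cfg)
        kept = filter_maf(ds.genotypes, 0.10)
        fraction = kept.n_loci / ds.genotypes.n_loci
        assert abs(fraction - 0.889) < 0.04

    def test_planted_causal_locus_is_top_hit(self):
        cfg = SimulationConfig(
            n_strains=113, n_loci=150, n_genes=10, n_causal=1, beta=3.0,
            causal_maf=0.4, n_cis=0, partner_rho=0.0, seed=29,
        )
        ds = simulate_population(cfg)
        phen = bin_by_mean(ds.expression, ds.truth.focal_gene)
        records = run_gwas(filter_maf(ds.genotypes, 0.10), phen)
        best = min(records, key=lambda r: r.p_nominal)
        assert best.locus.id == ds.truth.causal[0].locus_id

    def test_partner_gene_correlates_with_focal(self):
        cfg = SimulationConfig(n_strains=113, n_loci=50, n_genes=30,
                               partner_rho=0.8, seed=31)
        ds = simulate_population(cfg)
        focal = np.log2(ds.expression.row("focal"))
        partner = np.log2(ds.expression.row("partner"))
        assert np.corrcoef(focal, partner)[0, 1] > 0.6

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValidationError):
            SimulationConfig(n_loci=3, n_causal=2, n_cis=2)
        with pytest.raises(ValidationError):
            SimulationConfig(n_genes=2, n_cis=3)
        with pytest.raises(ValidationError):
            SimulationConfig(sigma=0.0)


class TestSimulateNull:
    def test_no_planted_structure(self):
        ds = simulate_null(SimulationConfig(n_strains=60, n_loci=80, n_genes=20,
                                            seed=3))
        assert ds.truth.causal == [] and ds.truth.cis == []
        assert ds.truth.partner_gene is None

    def test_null_pvalues_roughly_uniform(self):
        ds = simulate_null(SimulationConfig(n_strains=113, n_loci=300, n_genes=3,
                                            n_causal=0, n_cis=0, partner_rho=0.0,
                                            seed=17))
        phen = bin_by_mean(ds.expression, ds.truth.focal_gene)
        records = run_gwas(filter_maf(ds.genotypes, 0.10), phen)
        pvals = np.array([r.p_nominal for r in records])
        # discrete support makes P stochastically larger than uniform;
        # anti-conservatism would push these fractions above alpha
        for alpha in (0.05, 0.2, 0.5):
            frac = (pvals <= alpha).mean()
            assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / pvals.size)


class TestWriteDataset:
    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_strains=25, n_loci=40, n_genes=12, n_causal=1,
                               n_cis=2, causal_maf=0.3, seed=5)
        ds = simulate_population(cfg)
        write_dataset(ds, tmp_path / "d")
        G, expr, truth = read_dataset(tmp_path / "d")
        assert G == ds.genotypes
        assert expr == ds.expression
        assert truth == ds.truth

    def test_truth_rows_match_config(self, tmp_path):
        cfg = SimulationConfig(n_strains=20, n_loci=30, n_genes=10, n_causal=2,
                               n_cis=3, causal_maf=0.3, seed=6)
        write_dataset(simulate_population(cfg), tmp_path / "d")
        lines = (tmp_path / "d" / "truth.tsv").read_text().splitlines()
        kinds = [l.split("\t")[0] for l in lines[1:]]
        assert kinds.count("trans") == 2 and kinds.count("cis") == 3

    def test_null_truth_is_header_plus_nothing(self, tmp_path):
        ds = simulate_null(SimulationConfig(n_strains=10, n_loci=5, n_genes=3,
                                            n_causal=0, n_cis=0, partner_rho=0.0,
                                            seed=2))
        write_dataset(ds, tmp_path / "d")
        lines = (tmp_path / "d" / "truth.tsv").read_text().splitlines()
        assert len(lines) == 1

    def test_fixed_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_strains=15, n_loci=20, n_genes=8, seed=11)
        write_dataset(simulate_population(cfg), tmp_path / "a")
        write_dataset(simulate_population(cfg), tmp_path / "b")
        for name in ("genotypes.tsv", "expression.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
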