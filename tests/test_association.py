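import numpy as np
import pytest
from scipy import stats

from conftest import random_genotype_matrix
from hapgwas.association import (
    associate_locus,
    contingency_table,
    fisher_exact,
    fisher_two_sided_from_margins,
    manhattan_table,
    run_gwas,
)
from hapgwas.errors import PreconditionError
from hapgwas.phenotype_binning import bin_by_mean
from hapgwas.types import BinaryPhenotype, ExpressionMatrix
from oracles import fisher_two_sided_exact


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[3, 0], [0, 3]], 0.1),          # 2 of the 20 margin-fixed tables
            ([[2, 2], [2, 2]], 1.0),          # observed table is the mode
            ([[5, 0], [0, 5]], 2 / 252),      # C(10,5)=252, two extreme tables
        ],
    )
    def test_worked_examples(self, table, expected):
        assert fisher_exact(table) == pytest.approx(expected, abs=1e-12)

    def test_matches_exact_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            t = rng.integers(0, 9, size=(2, 2))
            if t.sum() == 0:
                continue
            expected = float(fisher_two_sided_exact(t.tolist()))
            assert fisher_exact(t) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_two_sided(self):
        # independent library cross-check on tables without near-ties
        rng = np.random.default_rng(1)
        for _ in range(100):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(
                stats.fisher_exact(t).pvalue, rel=1e-9
            )

    def test_row_and_column_swap_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            t = rng.integers(0, 10, size=(2, 2))
            if t.sum() == 0:
                continue
            p = fisher_exact(t)
            assert fisher_exact(t[::-1, :]) == pytest.approx(p, abs=1e-15)
            assert fisher_exact(t[:, ::-1]) == pytest.approx(p, abs=1e-15)

    def test_input_validation(self):
        with pytest.raises(PreconditionError):
            fisher_exact([[1, -1], [0, 2]])
        with pytest.raises(PreconditionError):
            fisher_exact([[0, 0], [0, 0]])

    def test_vectorized_margins_agree_with_scalar(self):
        rng = np.random.default_rng(3)
        tables = rng.integers(0, 8, size=(50, 2, 2)) + 1
        a = tables[:, 0, 0]
        m1 = tables[:, 0, :].sum(axis=1)
        n = tables.sum(axis=(1, 2))
        h = tables[:, :, 0].sum(axis=1)
        vec = fisher_two_sided_from_margins(a, m1, n, h)
        for i, t in enumerate(tables):
            assert vec[i] == fisher_exact(t)


class TestContingency:
    def test_perfect_split(self, small_genotypes, small_phenotype):
        locus = small_genotypes.loci[0]
        counts = contingency_table(
            small_genotypes.calls[:, 0], small_genotypes.strains,
            small_phenotype, (locus.alleles[0], locus.alleles[1]),
        )
        assert counts.tolist() == [[3, 0], [0, 3]]

    def test_missing_call_drops_strain_from_this_locus_only(
        self, small_genotypes, small_phenotype
    ):
        calls = small_genotypes.calls[:, 0].copy()
        calls[0] = "."
        counts = contingency_table(
            calls, small_genotypes.strains, small_phenotype, ("A", "G")
        )
        assert counts.sum() == 5 and counts.tolist() == [[2, 0], [0, 3]]

    def test_no_shared_strains(self, small_genotypes):
        phen = BinaryPhenotype("focal", 1.0, {"zz": "high", "zy": "low"})
        with pytest.raises(PreconditionError):
            contingency_table(
                small_genotypes.calls[:, 0], small_genotypes.strains, phen, ("A", "G")
            )


class TestRunGwas:
    def test_perfectly_coinherited_locus(self, small_genotypes, small_phenotype):
        records = run_gwas(small_genotypes, small_phenotype)
        assert len(records) == small_genotypes.n_loci
        assert [r.locus.id for r in records] == ["snp1", "snp2", "snp3"]
        r = records[0]
        assert r.p_nominal == pytest.approx(0.1, abs=1e-12)
        assert r.high_allele == "A"  # the A-carriers are the high strains
        assert r.neg_log10_p == pytest.approx(1.0, abs=1e-12)

    def test_balanced_locus_is_null(self, small_phenotype):
        from hapgwas.types import GenotypeMatrix

        # allele proportions identical in both bins: 2 A + 1 G in each
        calls = np.array([["A"], ["A"], ["G"], ["A"], ["A"], ["G"]])
        G = GenotypeMatrix.from_calls(
            [f"s{i}" for i in range(1, 7)], [("bal", 1, 1)], calls
        )
        (r,) = run_gwas(G, small_phenotype)
        assert r.p_nominal == pytest.approx(1.0)
        assert r.high_allele is None  # identical proportions in both bins

    def test_strain_order_irrelevant(self, small_genotypes, small_phenotype):
        records = run_gwas(small_genotypes, small_phenotype)
        order = [3, 0, 5, 1, 4, 2]
        from hapgwas.types import GenotypeMatrix

        G2 = GenotypeMatrix(
            strains=[small_genotypes.strains[i] for i in order],
            loci=small_genotypes.loci,
            calls=small_genotypes.calls[order, :],
        )
        records2 = run_gwas(G2, small_phenotype)
        assert [(r.p_nominal, r.high_allele) for r in records] == [
            (r.p_nominal, r.high_allele) for r in records2
        ]

    def test_empty_locus_set_warns_and_returns_empty(self, small_genotypes,
                                                     small_phenotype, caplog):
        G0 = small_genotypes.subset_loci([])
        with caplog.at_level("WARNING"):
            assert run_gwas(G0, small_phenotype) == []
        assert "empty locus set" in caplog.text

    def test_null_pvalues_not_anticonservative(self):
        # expression independent of genotype: P(p <= alpha) <= ~alpha
        rng = np.random.default_rng(9)
        G = random_genotype_matrix(rng, n_strains=60, n_loci=150)
        from hapgwas.variant_filtering import filter_maf

        G = filter_maf(G, 0.2)
        vals = rng.lognormal(3, 1, 60)
        expr = ExpressionMatrix(
            genes=["focal"], strains=G.strains, values=vals[None, :]
        )
        phen = bin_by_mean(expr, "focal")
        pvals = np.array([r.p_nominal for r in run_gwas(G, phen)])
        for alpha in (0.01, 0.05, 0.2):
            assert (pvals <= alpha).mean() <= alpha + 3 * np.sqrt(
                alpha * (1 - alpha) / pvals.size
            )


class TestManhattan:
    def test_sorted_by_genome_coordinate(self, small_genotypes, small_phenotype):
        records = run_gwas(small_genotypes, small_phenotype)
        table = manhattan_table(records[::-1])
        assert list(table["linkage_group"]) == [1, 2, 7]
        assert list(table["position"]) == [100, 2000, 30000]
        assert table["neg_log10_p"].iloc[0] == pytest.approx(1.0)

    def test_neg_log10_base_ten(self, small_genotypes, small_phenotype):
        records = run_gwas(small_genotypes, small_phenotype)
        for r in records:
            assert r.neg_log10_p == pytest.approx(-np.log10(r.p_nominal))

    def test_requires_records(self):
        with pytest.raises(PreconditionError):
            manhattan_table([])
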