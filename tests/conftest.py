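import numpy as np
import pytest

from hapgwas.types import ExpressionMatrix, GenotypeMatrix
from hapgwas.phenotype_binning import bin_by_mean


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """6 strains x 3 loci; locus snp1 perfectly splits the strains."""
    calls = np.array(
        [
            # snp1 snp2 snp3
            ["A", "C", "G"],
            ["A", "C", "T"],
            ["A", "T", "G"],
            ["G", "C", "G"],
            ["G", "T", "T"],
            ["G", "C", "G"],
        ]
    )
    return GenotypeMatrix.from_calls(
        [f"s{i}" for i in range(1, 7)],
        [("snp1", 1, 100), ("snp2", 2, 2000), ("snp3", 7, 30000)],
        calls,
    )


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    """Focal gene splits the 6 strains 3 high / 3 low around its mean (25)."""
    values = np.array(
        [
            [40.0, 35.0, 30.0, 20.0, 15.0, 10.0],  # focal
            [80.0, 70.0, 60.0, 40.0, 30.0, 20.0],  # tracks focal
            [5.0, 9.0, 2.0, 7.0, 3.0, 8.0],        # unrelated
        ]
    )
    return ExpressionMatrix(
        genes=["focal", "tracker", "noise"],
        strains=[f"s{i}" for i in range(1, 7)],
        values=values,
    )


@pytest.fixture
def small_phenotype(small_expression):
    return bin_by_mean(small_expression, "focal")


def random_genotype_matrix(rng: np.random.Generator, n_strains=20, n_loci=30,
                           missing_rate=0.0) -> GenotypeMatrix:
    """Random matrix with per-locus MAF uniform on (0.02, 0.5)."""
    mafs = rng.uniform(0.02, 0.5, n_loci)
    minor = rng.random((n_strains, n_loci)) < mafs
    calls = np.where(minor, "G", "A").astype("<U1")
    if missing_rate:
        calls[rng.random((n_strains, n_loci)) < missing_rate] = "."
    return GenotypeMatrix.from_calls(
        [f"s{i}" for i in range(n_strains)],
        [(f"l{j}", 1 + j % 7, j + 1) for j in range(n_loci)],
        calls,
    )
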