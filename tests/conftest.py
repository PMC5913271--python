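import numpy as np
import pytest

from snpdist import (
    GenotypeMatrix,
    PhenotypeTable,
    VariantRecord,
    worked_example_fixture,
)


@pytest.fixture
def worked_example() -> GenotypeMatrix:
    """The three-subject, eight-SNP worked example."""
    return worked_example_fixture()


@pytest.fixture
def worked_example_phenotypes() -> PhenotypeTable:
    return PhenotypeTable({"X": "case", "Y": "control", "Z": "control"})


def random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_variants: int,
    missing_rate: float = 0.0,
    n_alleles: int = 2,
) -> GenotypeMatrix:
    """Random biallelic-or-more genotype matrix for property tests."""
    a = rng.integers(0, n_alleles, size=(n_samples, n_variants, 2), dtype=np.int16)
    a.sort(axis=2)
    if missing_rate > 0:
        miss = rng.random((n_samples, n_variants)) < missing_rate
        a[miss] = -1
    symbols = ("A", "C", "G", "T")
    variants = [
        VariantRecord(f"v{j}", alleles=symbols[:n_alleles]) for j in range(n_variants)
    ]
    return GenotypeMatrix([f"s{i}" for i in range(n_samples)], variants, a)
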