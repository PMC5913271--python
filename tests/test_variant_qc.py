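"""MAF computation, exact HWE test, QC filtering, MAF classification."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpdist import (
    QcThresholds,
    apply_qc,
    classify_by_maf,
    classify_maf,
    compute_maf,
    compute_mafs,
    hwe_exact_test,
    worked_example_fixture,
)
from snpdist.genotype_io import GenotypeMatrix, PhenotypeTable, VariantRecord
from snpdist.variant_qc import class_variant_sets

from conftest import random_matrix


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def test_maf_worked_example_snp1(worked_example):
    # SNP1 alleles over X={A,T}, Y={A,A}, Z={A,A}: A x5, T x1
    assert compute_maf(worked_example, "SNP1") == pytest.approx(1 / 6)


def test_maf_monomorphic_is_zero(worked_example):
    assert compute_maf(worked_example, "SNP2") == 0.0  # everyone GG


def test_maf_direct_count_on_generated_fixture():
    # 50 samples with exactly 37 alt / 63 ref alleles... constructed directly:
    # 13 het + 12 hom-alt gives 13 + 24 = 37 alt alleles of 100
    grid = np.zeros((50, 1, 2), dtype=np.int16)
    grid[:13, 0, 1] = 1
    grid[13:25, 0, :] = 1
    m = GenotypeMatrix(
        [f"s{i}" for i in range(50)], [VariantRecord("v", alleles=("A", "G"))], grid
    )
    assert compute_maf(m, 0) == pytest.approx(0.37)


def test_maf_all_missing_errors():
    grid = np.full((3, 1, 2), -1, dtype=np.int16)
    m = GenotypeMatrix(["a", "b", "c"], [VariantRecord("v", alleles=("A", "G"))], grid)
    with pytest.raises(ValueError, match="missing"):
        compute_maf(m, 0)


def test_maf_invariant_under_ref_alt_relabeling():
    rng = np.random.default_rng(3)
    m = random_matrix(rng, 30, 20, missing_rate=0.1)
    flipped = GenotypeMatrix(
        list(m.sample_ids),
        list(m.variants),
        np.where(m.allele_idx >= 0, 1 - m.allele_idx[:, :, ::-1], -1),
    )
    for j in range(m.n_variants):
        assert compute_maf(m, j) == pytest.approx(compute_maf(flipped, j))


def test_compute_mafs_matches_scalar_path():
    rng = np.random.default_rng(5)
    m = random_matrix(rng, 40, 25, missing_rate=0.05, n_alleles=3)
    vec = compute_mafs(m)
    for j in range(m.n_variants):
        assert vec[j] == pytest.approx(compute_maf(m, j))


# ---------------------------------------------------------------------------
# HWE exact test vs full-enumeration oracle
# ---------------------------------------------------------------------------


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Independent exact-rational enumeration of the conditional HWE test."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    prob = {}
    for h in range(min(n_A, 2 * n - n_A) % 2, min(n_A, 2 * n - n_A) + 1, 2):
        hom_a = (min(n_A, 2 * n - n_A) - h) // 2
        hom_A = n - h - hom_a
        if hom_A < 0:
            continue
        num = (
            Fraction(math.factorial(n))
            / (math.factorial(hom_A) * math.factorial(h) * math.factorial(hom_a))
            * 2**h
        )
        prob[h] = num
    total = sum(prob.values())
    obs = prob[n_Aa]
    return float(sum(p for p in prob.values() if p <= obs) / total)


@pytest.mark.parametrize(
    "counts",
    [(0, 2, 0), (1, 0, 0), (25, 50, 25), (100, 0, 100), (3, 1, 7), (0, 1, 40)],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)


def test_hwe_single_attainable_outcome_is_one():
    assert hwe_exact_test(1, 0, 0) == 1.0
    assert hwe_exact_test(0, 2, 0) == 1.0  # observed table is the most probable


def test_hwe_extreme_departure_is_tiny():
    assert hwe_exact_test(100, 0, 100) < 1e-6


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


def test_hwe_log_space_branch_agrees_with_exact():
    import snpdist.variant_qc as vq

    counts = (5200, 9000, 4100)  # ~36k alleles: log-gamma branch
    exact_limit = vq._EXACT_ALLELE_LIMIT
    try:
        vq._EXACT_ALLELE_LIMIT = 10**9
        exact = hwe_exact_test(*counts)
    finally:
        vq._EXACT_ALLELE_LIMIT = exact_limit
    assert hwe_exact_test(*counts) == pytest.approx(exact, rel=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=40),
    st.integers(min_value=0, max_value=40),
    st.integers(min_value=0, max_value=40),
)
def test_hwe_property_matches_oracle(a, h, b):
    if a + h + b == 0:
        return
    p = hwe_exact_test(a, h, b)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(hwe_oracle(a, h, b), abs=1e-12)


# ---------------------------------------------------------------------------
# classification boundaries
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "maf,label",
    [
        (0.05, "common"),
        (0.005, "low_frequency"),
        (0.004999, "rare"),
        (0.0, "rare"),
        (0.5, "common"),
        (0.049999, "low_frequency"),
    ],
)
def test_maf_class_boundaries(maf, label):
    assert classify_maf(maf) == label


def test_classify_by_maf_partitions():
    rng = np.random.default_rng(0)
    mafs = rng.uniform(0, 0.5, 1000)
    ids = [f"v{i}" for i in range(1000)]
    labels, sets = classify_by_maf(ids, mafs)
    assert sum(len(s) for s in sets.values()) == 1000
    assert set().union(*sets.values()) == set(ids)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def _with_missing(matrix, j, rows):
    matrix.allele_idx[rows, j] = -1
    return matrix


def test_apply_qc_call_rate_removal():
    rng = np.random.default_rng(1)
    m = random_matrix(rng, 10, 5)
    _with_missing(m, 2, [0, 1, 2, 3])  # call rate 0.6 < 0.95
    filtered, cls = apply_qc(m)
    assert "v2" not in filtered.variant_ids
    assert cls[2].qc_fail_reasons == ["call_rate"]
    assert filtered.n_variants == 4


def test_apply_qc_multiallelic_removal():
    grid = np.zeros((10, 1, 2), dtype=np.int16)
    grid[0] = (0, 1)
    grid[1] = (1, 2)  # third allele observed
    m = GenotypeMatrix(
        [f"s{i}" for i in range(10)],
        [VariantRecord("v", alleles=("A", "C", "T"))],
        grid,
    )
    _, cls = apply_qc(m)
    assert cls[0].qc_fail_reasons == ["multiallelic"]


def test_apply_qc_hwe_removal():
    # 200 samples split hom/hom with no hets: HWE P ~ 0 by enumeration
    grid = np.zeros((200, 1, 2), dtype=np.int16)
    grid[100:] = 1
    m = GenotypeMatrix(
        [f"s{i}" for i in range(200)], [VariantRecord("v", alleles=("A", "G"))], grid
    )
    assert hwe_exact_test(100, 0, 100) < 1e-6
    filtered, cls = apply_qc(m, QcThresholds(hwe_sample_set="all"))
    assert cls[0].qc_fail_reasons == ["hwe"]
    assert filtered.n_variants == 0


def test_apply_qc_controls_only_uses_controls():
    # cases wildly out of HWE, controls in perfect HWE: controls-only passes
    grid = np.zeros((300, 1, 2), dtype=np.int16)
    grid[50:100] = 1  # cases (rows 0-99): 50 hom-ref, 50 hom-alt, no hets
    grid[150:250, 0, 1] = 1  # controls (rows 100-299): 100 het
    grid[250:300] = 1  # 50 hom-alt; remaining 50 controls hom-ref
    ids = [f"s{i}" for i in range(300)]
    m = GenotypeMatrix(ids, [VariantRecord("v", alleles=("A", "G"))], grid)
    pheno = PhenotypeTable(
        {s: ("case" if i < 100 else "control") for i, s in enumerate(ids)}
    )
    _, cls_controls = apply_qc(m, QcThresholds(), pheno)
    assert cls_controls[0].qc_pass
    _, cls_all = apply_qc(m, QcThresholds(hwe_sample_set="all"), pheno)
    assert cls_all[0].qc_fail_reasons == ["hwe"]


def test_apply_qc_retains_monomorphic_as_rare():
    grid = np.zeros((20, 1, 2), dtype=np.int16)
    m = GenotypeMatrix(
        [f"s{i}" for i in range(20)], [VariantRecord("v", alleles=("C",))], grid
    )
    filtered, cls = apply_qc(m)
    assert filtered.n_variants == 1
    assert cls[0].class_label == "rare"
    assert cls[0].maf == 0.0


def test_apply_qc_idempotent():
    rng = np.random.default_rng(9)
    m = random_matrix(rng, 30, 40, missing_rate=0.08)
    once, cls1 = apply_qc(m)
    twice, cls2 = apply_qc(once)
    assert twice.variant_ids == once.variant_ids
    assert np.array_equal(twice.allele_idx, once.allele_idx)
    assert all(c.qc_pass for c in cls2)


def test_partition_invariant_matches_qc_pass_total():
    rng = np.random.default_rng(13)
    m = random_matrix(rng, 50, 60, missing_rate=0.1)
    filtered, cls = apply_qc(m)
    sets = class_variant_sets(cls)
    assert sum(len(s) for s in sets.values()) == filtered.n_variants
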