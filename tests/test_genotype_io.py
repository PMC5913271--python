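"""Genotype I/O: plain-text tables, VCF, PLINK binary, phenotypes."""

import numpy as np
import pytest

from snpdist import (
    GenotypeCall,
    PhenotypeTable,
    VariantRecord,
    concat_samples,
    read_genotype_table,
    read_phenotypes,
    read_plink_binary,
    read_vcf,
    worked_example_fixture,
    write_genotype_table,
    write_vcf,
)
from snpdist.genotype_io import GenotypeParseError

from conftest import random_matrix


# ---------------------------------------------------------------------------
# calls and basic model
# ---------------------------------------------------------------------------


def test_genotype_call_is_order_insensitive():
    assert GenotypeCall.of("A", "G") == GenotypeCall.of("G", "A")
    assert not GenotypeCall.of("A", "G").missing
    assert GenotypeCall().missing


def test_genotype_call_rejects_single_allele():
    with pytest.raises(ValueError):
        GenotypeCall.of("A")


def test_variant_record_rejects_nonpositive_position():
    with pytest.raises(ValueError):
        VariantRecord("v1", position=0)


# ---------------------------------------------------------------------------
# plain-text table
# ---------------------------------------------------------------------------

WORKED_EXAMPLE_TEXT = """\
sample\tSNP1\tSNP2\tSNP3\tSNP4\tSNP5\tSNP6\tSNP7\tSNP8
\t(A/T)\t(G/T)\t(C/G)\t(C/T)\t(C/T)\t(A/G)\t(A/C)\t(C/T)
X\tAT\tGG\tCG\tCC\tCC\tAG\tAC\tTT
Y\tAA\tGG\tCC\tTT\tCT\tGG\tCC\tCT
Z\tAA\tGG\tCC\tCC\tCT\tAA\tCC\tTT
"""


def test_read_table_reproduces_worked_example(tmp_path):
    path = tmp_path / "t1.tsv"
    path.write_text(WORKED_EXAMPLE_TEXT)
    m = read_genotype_table(path)
    assert m.sample_ids == ["X", "Y", "Z"]
    assert m.n_variants == 8
    assert m.call("X", "SNP1") == GenotypeCall.of("A", "T")
    assert m.call("Y", "SNP4") == GenotypeCall.of("T", "T")
    assert not m.missing_mask.any()
    assert m.equals(worked_example_fixture())


def test_read_table_annotation_stored_on_variant(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text("id,SNP1(A/T),SNP2(C/G)\ns1,AA,CC\n")
    m = read_genotype_table(path)
    assert m.variants[0].ref_allele == "A"
    assert m.variants[0].alt_alleles == ("T",)


def test_read_table_empty_body_gives_zero_samples(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("sample\t" + "\t".join(f"SNP{i}" for i in range(1, 9)) + "\n")
    m = read_genotype_table(path)
    assert m.n_samples == 0
    assert m.n_variants == 8


def test_read_table_invalid_symbol_names_offending_cell(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("sample\tSNP1\ts1\tAZ\n".replace("\ts1", "\ns1"))
    with pytest.raises(GenotypeParseError, match="s1.*SNP1|SNP1.*s1"):
        read_genotype_table(path)


def test_read_table_rejects_duplicate_ids(tmp_path):
    p1 = tmp_path / "dup_sample.tsv"
    p1.write_text("sample\tSNP1\na\tAA\na\tAC\n")
    with pytest.raises(GenotypeParseError, match="duplicate sample"):
        read_genotype_table(p1)
    p2 = tmp_path / "dup_variant.tsv"
    p2.write_text("sample\tSNP1\tSNP1\na\tAA\tAC\n")
    with pytest.raises(GenotypeParseError, match="duplicate variant"):
        read_genotype_table(p2)


def test_read_table_missing_token(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("sample\tSNP1\tSNP2\ns1\tNN\tAC\n")
    m = read_genotype_table(path)
    assert m.call(0, 0).missing
    assert m.call(0, 1) == GenotypeCall.of("A", "C")


def test_table_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    m = random_matrix(rng, 6, 10, missing_rate=0.2, n_alleles=3)
    path = tmp_path / "rt.tsv"
    write_genotype_table(m, path)
    back = read_genotype_table(path)
    assert back.sample_ids == m.sample_ids
    assert back.variant_ids == m.variant_ids
    # call grids agree cell by cell (index coding may legitimately differ)
    for i in range(m.n_samples):
        for j in range(m.n_variants):
            assert back.call(i, j) == m.call(i, j)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_SMALL = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb
1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/1\t1|0
1\t200\tv2\tC\tT\t.\t.\t.\tGT\t./.\t0/.
1\t300\tv3\tG\tA,T\t.\t.\t.\tGT\t1/2\t0/0
"""


def test_read_vcf_phase_and_order_insensitive(tmp_path):
    path = tmp_path / "s.vcf"
    path.write_text(VCF_SMALL)
    m = read_vcf(path)
    assert m.call("a", "v1") == m.call("b", "v1") == GenotypeCall.of("A", "G")


def test_read_vcf_missing_and_half_calls(tmp_path):
    path = tmp_path / "s.vcf"
    path.write_text(VCF_SMALL)
    m = read_vcf(path)
    assert m.call("a", "v2").missing
    assert m.call("b", "v2").missing  # half-call treated as missing


def test_read_vcf_keeps_multiallelic_sites(tmp_path):
    path = tmp_path / "s.vcf"
    path.write_text(VCF_SMALL)
    m = read_vcf(path)
    assert m.call("a", "v3") == GenotypeCall.of("A", "T")
    assert m.variants[2].alleles == ("G", "A", "T")


def test_read_vcf_without_gt_errors(tmp_path):
    path = tmp_path / "nogt.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t100\tv1\tA\tG\t.\t.\tDP=3\n"
    )
    with pytest.raises(GenotypeParseError, match="GT"):
        read_vcf(path)


def test_vcf_write_read_round_trip(tmp_path):
    rng = np.random.default_rng(11)
    m = random_matrix(rng, 3, 5, missing_rate=0.15)
    # give the variants coordinates so the round trip is exact
    m.variants = [
        VariantRecord(v.variant_id, "1", j + 1, v.alleles)
        for j, v in enumerate(m.variants)
    ]
    path = tmp_path / "rt.vcf"
    write_vcf(m, path)
    back = read_vcf(path)
    assert back.equals(m)


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------


def _write_plink(tmp_path, bed_bytes, fam_rows, bim_rows, prefix="toy"):
    (tmp_path / f"{prefix}.bed").write_bytes(bed_bytes)
    (tmp_path / f"{prefix}.fam").write_text("\n".join(fam_rows) + "\n")
    (tmp_path / f"{prefix}.bim").write_text("\n".join(bim_rows) + "\n")
    return tmp_path / prefix


# 4 samples x 3 variants, variant-major. Codes per variant (sample order):
#   v1: hom-A1, missing, het, hom-A2   -> byte 0b11100100 = 0xE4
#   v2: het, het, hom-A1, hom-A1       -> byte 0b00001010 = 0x0A
#   v3: hom-A2, hom-A2, hom-A2, missing-> byte 0b01111111 = 0x7F
TOY_BED = bytes([0x6C, 0x1B, 0x01, 0xE4, 0x0A, 0x7F])
TOY_FAM = [
    "f1 s1 0 0 1 2",
    "f2 s2 0 0 1 1",
    "f3 s3 0 0 2 2",
    "f4 s4 0 0 2 1",
]
TOY_BIM = [
    "1 v1 0 100 A G",
    "1 v2 0 200 C T",
    "2 v3 0 300 G A",
]


def test_read_plink_decodes_two_bit_codes(tmp_path):
    prefix = _write_plink(tmp_path, TOY_BED, TOY_FAM, TOY_BIM)
    m, pheno = read_plink_binary(prefix)
    assert m.sample_ids == ["s1", "s2", "s3", "s4"]
    # hand-decoded expectations
    assert m.call("s1", "v1") == GenotypeCall.of("A", "A")
    assert m.call("s2", "v1").missing
    assert m.call("s3", "v1") == GenotypeCall.of("A", "G")
    assert m.call("s4", "v1") == GenotypeCall.of("G", "G")
    assert m.call("s1", "v2") == GenotypeCall.of("C", "T")
    assert m.call("s3", "v2") == GenotypeCall.of("C", "C")
    assert m.call("s3", "v3") == GenotypeCall.of("A", "A")
    assert m.call("s4", "v3").missing


def test_read_plink_fam_phenotype_coding(tmp_path):
    prefix = _write_plink(tmp_path, TOY_BED, TOY_FAM, TOY_BIM)
    _, pheno = read_plink_binary(prefix)
    assert [pheno[s] for s in ("s1", "s2", "s3", "s4")] == [
        "case",
        "control",
        "case",
        "control",
    ]


def test_read_plink_all_missing_payload(tmp_path):
    bed = bytes([0x6C, 0x1B, 0x01, 0x55, 0x55, 0x55])  # 01 everywhere
    prefix = _write_plink(tmp_path, bed, TOY_FAM, TOY_BIM)
    m, _ = read_plink_binary(prefix)
    assert m.missing_mask.all()


def test_read_plink_sample_major_layout(tmp_path):
    # the TOY grid stored sample-major: one byte per sample, variant k in
    # bits 2k..2k+1 (read the literals high-to-low as v3,v2,v1)
    rows = [0b00_11_10_00, 0b00_11_10_01, 0b00_11_00_10, 0b00_01_00_11]
    bed = bytes([0x6C, 0x1B, 0x00] + rows)
    prefix = _write_plink(tmp_path, bed, TOY_FAM, TOY_BIM, prefix="sm")
    m, _ = read_plink_binary(prefix)
    vm, _ = read_plink_binary(_write_plink(tmp_path, TOY_BED, TOY_FAM, TOY_BIM))
    assert m.equals(vm)


def test_read_plink_bad_magic_and_dimensions(tmp_path):
    prefix = _write_plink(tmp_path, b"\x00\x00\x01\x00", TOY_FAM, TOY_BIM)
    with pytest.raises(GenotypeParseError, match="magic"):
        read_plink_binary(prefix)
    prefix = _write_plink(tmp_path, TOY_BED[:-1], TOY_FAM, TOY_BIM, prefix="short")
    with pytest.raises(GenotypeParseError, match="payload"):
        read_plink_binary(prefix)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def test_read_phenotypes_tokens(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text("X,case\nY,control\nZ,control\n")
    t = read_phenotypes(path)
    assert t.cases == ["X"]
    assert sorted(t.controls) == ["Y", "Z"]


def test_read_phenotypes_numeric_coding_equivalent(tmp_path):
    p1 = tmp_path / "w.csv"
    p1.write_text("a,case\nb,control\n")
    p2 = tmp_path / "n.csv"
    p2.write_text("a,2\nb,1\n")
    assert read_phenotypes(p1).status == read_phenotypes(p2).status


def test_read_phenotypes_unknown_token_and_conflict(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text("a,maybe\n")
    with pytest.raises(GenotypeParseError, match="maybe"):
        read_phenotypes(bad)
    conflict = tmp_path / "conflict.csv"
    conflict.write_text("a,case\na,control\n")
    with pytest.raises(GenotypeParseError, match="conflicting"):
        read_phenotypes(conflict)


def test_phenotype_table_rejects_bad_levels():
    with pytest.raises(ValueError):
        PhenotypeTable({"a": "patient"})


def test_concat_samples_remaps_allele_tables():
    a = worked_example_fixture()
    b = worked_example_fixture()
    b.sample_ids = ["P", "Q", "R"]
    both = concat_samples(a, b)
    assert both.n_samples == 6
    assert both.call("P", "SNP1") == a.call("X", "SNP1")
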