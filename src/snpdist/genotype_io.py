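"""Genotype matrix I/O and the shared data model.

A genotype call is an *unordered* pair of alleles: diploid array and exome-chip
genotypes are unphased, so ``A/G`` and ``G/A`` are the same call.  Internally a
:class:`GenotypeMatrix` stores every call as a sorted pair of small integer
indices into the per-variant allele table, with ``(-1, -1)`` marking a missing
call; this keeps pairwise-distance kernels fully vectorisable.

Supported formats:

* plain-text genotype tables (one row per subject, one two-allele genotype per
  variant, optional ``(ref/alt)`` allele annotation) — read and write;
* multi-sample VCF 4.x with a GT field (phase is discarded on read) — read and
  write;
* PLINK 1 binary filesets (``.bed``/``.bim``/``.fam``) — read;
* two-column phenotype files mapping sample id to case/control status.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: sentinel allele index for a missing call
MISSING = -1

CASE = "case"
CONTROL = "control"
UNKNOWN = "unknown"


class GenotypeParseError(ValueError):
    """Raised when an input file cannot be interpreted as genotypes."""


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid genotype: two allele strings, or nothing if missing.

    Equality is order-insensitive because alleles are stored sorted.
    """

    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.alleles) not in (0, 2):
            raise ValueError(
                f"a genotype call holds exactly two alleles or none, got {self.alleles!r}"
            )
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @classmethod
    def of(cls, *alleles: str) -> "GenotypeCall":
        return cls(tuple(alleles))

    @property
    def missing(self) -> bool:
        return len(self.alleles) == 0

    def __str__(self) -> str:
        return "/".join(self.alleles) if self.alleles else "./."


@dataclass(frozen=True)
class VariantRecord:
    """Metadata for one variant.

    ``alleles`` is the ordered allele table the matrix's integer codes index
    into; by convention the reference allele, when known, sits first.
    """

    variant_id: str
    chromosome: str | None = None
    position: int | None = None
    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position is not None and self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")

    @property
    def ref_allele(self) -> str | None:
        return self.alleles[0] if self.alleles else None

    @property
    def alt_alleles(self) -> tuple[str, ...]:
        return self.alleles[1:]


@dataclass
class GenotypeMatrix:
    """Samples x variants grid of unordered diploid calls.

    ``allele_idx`` has shape ``(n_samples, n_variants, 2)``; each pair is
    sorted ascending and indexes the variant's allele table; missing calls are
    ``(-1, -1)``.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    allele_idx: np.ndarray

    def __post_init__(self) -> None:
        self.allele_idx = np.asarray(self.allele_idx, dtype=np.int16)
        expected = (len(self.sample_ids), len(self.variants), 2)
        if self.allele_idx.shape != expected:
            raise ValueError(
                f"call grid shape {self.allele_idx.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        vids = [v.variant_id for v in self.variants]
        if len(set(vids)) != len(vids):
            dupes = sorted({v for v in vids if vids.count(v) > 1})
            raise ValueError(f"duplicate variant ids: {dupes}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_variants) mask of missing calls."""
        return self.allele_idx[:, :, 0] < 0

    def call(self, sample: int | str, variant: int | str) -> GenotypeCall:
        i = self.sample_ids.index(sample) if isinstance(sample, str) else sample
        j = self.variant_ids.index(variant) if isinstance(variant, str) else variant
        a, b = self.allele_idx[i, j]
        if a < 0:
            return GenotypeCall()
        table = self.variants[j].alleles
        return GenotypeCall.of(table[a], table[b])

    def call_rates(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_variants)
        return 1.0 - self.missing_mask.mean(axis=0)

    # -- subsetting --------------------------------------------------------

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        """Restrict to the given variants, preserving this matrix's order."""
        wanted = set(variant_ids)
        unknown = wanted - set(self.variant_ids)
        if unknown:
            raise KeyError(f"unknown variant ids: {sorted(unknown)[:5]}")
        idx = [j for j, v in enumerate(self.variants) if v.variant_id in wanted]
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.variants[j] for j in idx],
            self.allele_idx[:, idx, :].copy(),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        unknown = [s for s in sample_ids if s not in order]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown[:5]}")
        idx = [order[s] for s in sample_ids]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.variants),
            self.allele_idx[idx, :, :].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.variant_ids == other.variant_ids
            and [v.alleles for v in self.variants] == [v.alleles for v in other.variants]
            and np.array_equal(self.allele_idx, other.allele_idx)
        )


@dataclass
class PhenotypeTable:
    """Maps sample id to ``case`` / ``control`` (``unknown`` is tolerated on
    input and excluded by the pipeline with a logged count)."""

    status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s for s in self.status.values() if s not in (CASE, CONTROL, UNKNOWN)}
        if bad:
            raise ValueError(f"invalid phenotype levels: {sorted(bad)}")

    def __getitem__(self, sample_id: str) -> str:
        return self.status[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.status

    def __len__(self) -> int:
        return len(self.status)

    @property
    def cases(self) -> list[str]:
        return [s for s, v in self.status.items() if v == CASE]

    @property
    def controls(self) -> list[str]:
        return [s for s, v in self.status.items() if v == CONTROL]

    @property
    def unknowns(self) -> list[str]:
        return [s for s, v in self.status.items() if v == UNKNOWN]


# ---------------------------------------------------------------------------
# plain-text genotype tables
# ---------------------------------------------------------------------------

_HEADER_ANNOT = re.compile(r"^(?P<name>.*?)\s*\((?P<alleles>[^()\s]+/[^()\s]+)\)$")
_ANNOT_CELL = re.compile(r"^\([^()\s]+/[^()\s]+\)$")


def _split_line(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        return line.split()
    return [c.strip() for c in line.split(delimiter)]


def _sniff_delimiter(header: str) -> str | None:
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return None  # any whitespace


def read_genotype_table(
    path,
    *,
    delimiter: str | None = None,
    missing_token: str = "NN",
    alphabet: str = "ACGT",
) -> GenotypeMatrix:
    """Read a plain-text genotype table.

    Layout: a header row naming the variants (optionally annotated like
    ``SNP1(A/T)``, or followed by a separate annotation row of ``(A/T)``
    cells), then one row per subject holding one two-character genotype per
    variant.  Missing genotypes are ``missing_token`` (default ``NN``) or
    ``./.``.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    delimiter = delimiter if delimiter is not None else _sniff_delimiter(lines[0])
    header = _split_line(lines[0], delimiter)
    if len(header) < 2:
        raise GenotypeParseError(f"{path}: header must name at least one variant")

    names: list[str] = []
    annots: list[tuple[str, ...] | None] = []
    for cell in header[1:]:
        m = _HEADER_ANNOT.match(cell)
        if m and m.group("name"):
            names.append(m.group("name"))
            annots.append(tuple(m.group("alleles").split("/")))
        else:
            names.append(cell)
            annots.append(None)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise GenotypeParseError(f"{path}: duplicate variant ids {dupes}")

    body = lines[1:]
    # A row whose genotype cells are all "(x/y)" is an allele-annotation row.
    if body:
        cells = _split_line(body[0], delimiter)
        gcells = cells[1:] if len(cells) == len(names) + 1 else cells
        if len(gcells) == len(names) and all(_ANNOT_CELL.match(c) for c in gcells):
            annots = [tuple(c.strip("()").split("/")) for c in gcells]
            body = body[1:]

    allele_tables: list[list[str]] = [list(a) if a else [] for a in annots]
    sample_ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    missing_tokens = {missing_token, "./.", ".."}
    for ln in body:
        cells = _split_line(ln, delimiter)
        if len(cells) != len(names) + 1:
            raise GenotypeParseError(
                f"{path}: row {cells[0] if cells else '?'!r} has {len(cells) - 1} "
                f"genotypes, expected {len(names)}"
            )
        sid = cells[0]
        if sid in sample_ids:
            raise GenotypeParseError(f"{path}: duplicate sample id {sid!r}")
        sample_ids.append(sid)
        row: list[tuple[int, int]] = []
        for j, token in enumerate(cells[1:]):
            if token in missing_tokens:
                row.append((MISSING, MISSING))
                continue
            if len(token) != 2:
                raise GenotypeParseError(
                    f"{path}: sample {sid!r}, variant {names[j]!r}: genotype "
                    f"{token!r} is not two alleles"
                )
            pair = []
            for sym in token:
                if alphabet and sym not in alphabet:
                    raise GenotypeParseError(
                        f"{path}: sample {sid!r}, variant {names[j]!r}: allele "
                        f"{sym!r} outside alphabet {alphabet!r}"
                    )
                table = allele_tables[j]
                if sym not in table:
                    table.append(sym)
                pair.append(table.index(sym))
            row.append((min(pair), max(pair)))
        rows.append(row)

    variants = [
        VariantRecord(name, alleles=tuple(allele_tables[j]))
        for j, name in enumerate(names)
    ]
    grid = (
        np.array(rows, dtype=np.int16)
        if rows
        else np.empty((0, len(names), 2), dtype=np.int16)
    )
    return GenotypeMatrix(sample_ids, variants, grid)


def write_genotype_table(
    matrix: GenotypeMatrix,
    path,
    *,
    delimiter: str = "\t",
    missing_token: str = "NN",
    annotate: bool = True,
) -> None:
    """Write the two-character-genotype table format (single-char alleles only)."""
    for v in matrix.variants:
        if any(len(a) != 1 for a in v.alleles):
            raise ValueError(
                f"{v.variant_id}: multi-character alleles cannot be written as a "
                "plain-text genotype table; use write_vcf"
            )
    header = ["sample"]
    for v in matrix.variants:
        if annotate and len(v.alleles) >= 2:
            header.append(f"{v.variant_id}({v.alleles[0]}/{'/'.join(v.alleles[1:])})")
        else:
            header.append(v.variant_id)
    out = [delimiter.join(header)]
    for i, sid in enumerate(matrix.sample_ids):
        cells = [sid]
        for j, v in enumerate(matrix.variants):
            a, b = matrix.allele_idx[i, j]
            cells.append(missing_token if a < 0 else v.alleles[a] + v.alleles[b])
        out.append(delimiter.join(cells))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path) -> GenotypeMatrix:
    """Read a multi-sample VCF 4.x into a :class:`GenotypeMatrix`.

    Phase separators are ignored (``0|1`` equals ``1/0``); half-calls and
    ``./.`` become missing; sites with any number of ALT alleles are retained
    (multiallelic filtering is the QC module's job).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise GenotypeParseError(f"cannot open VCF {path}: {exc}") from exc
    has_gt = any(
        h.type == "FORMAT" and h.info().get("ID") == "GT" for h in vcf.header_iter()
    )
    if not has_gt:
        raise GenotypeParseError(f"{path}: VCF has no GT FORMAT field")

    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if vid in seen:
            raise GenotypeParseError(f"{path}: duplicate variant id {vid!r}")
        seen.add(vid)
        variants.append(
            VariantRecord(
                vid,
                chromosome=rec.CHROM,
                position=rec.POS,
                alleles=(rec.REF, *rec.ALT),
            )
        )
        col = np.full((len(sample_ids), 2), MISSING, dtype=np.int16)
        for i, gt in enumerate(rec.genotypes):
            pair = gt[:-1]  # last element is the phased flag
            if len(pair) == 2 and min(pair) >= 0:
                col[i] = sorted(pair)
        rows.append(col)

    grid = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(sample_ids), 0, 2), dtype=np.int16)
    )
    return GenotypeMatrix(sample_ids, variants, grid)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal unphased VCF 4.2 (GT only)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids),
    ]
    for j, v in enumerate(matrix.variants):
        if not v.alleles:
            raise ValueError(f"{v.variant_id}: no allele table; cannot write VCF")
        chrom = v.chromosome or "1"
        pos = v.position or j + 1
        ref = v.alleles[0]
        alt = ",".join(v.alleles[1:]) if len(v.alleles) > 1 else "."
        gts = []
        for i in range(matrix.n_samples):
            a, b = matrix.allele_idx[i, j]
            gts.append("./." if a < 0 else f"{a}/{b}")
        lines.append(
            f"{chrom}\t{pos}\t{v.variant_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# 2-bit codes: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_CODE_TO_PAIR = np.array(
    [[0, 0], [MISSING, MISSING], [0, 1], [1, 1]], dtype=np.int16
)


def read_plink_binary(prefix) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Read a PLINK 1 ``.bed``/``.bim``/``.fam`` fileset.

    Returns the genotype matrix together with a phenotype table decoded from
    the sixth ``.fam`` column (2 = case, 1 = control, -9/0 = unknown).
    Both variant-major and sample-major ``.bed`` layouts are supported.
    """
    prefix = Path(prefix)
    fam_rows = [ln.split() for ln in (prefix.with_suffix(".fam")).read_text().splitlines() if ln.strip()]
    bim_rows = [ln.split() for ln in (prefix.with_suffix(".bim")).read_text().splitlines() if ln.strip()]
    buf = prefix.with_suffix(".bed").read_bytes()

    if buf[:2] != _BED_MAGIC:
        raise GenotypeParseError(f"{prefix}.bed: bad magic bytes {buf[:2]!r}")
    mode = buf[2]
    if mode not in (0, 1):
        raise GenotypeParseError(f"{prefix}.bed: unknown storage mode byte {mode}")

    n, m = len(fam_rows), len(bim_rows)
    sample_ids = [r[1] for r in fam_rows]
    if len(set(sample_ids)) != len(sample_ids):  # fall back to FID_IID
        sample_ids = [f"{r[0]}_{r[1]}" for r in fam_rows]
    variants = [
        VariantRecord(
            r[1],
            chromosome=r[0],
            position=int(r[3]) if int(r[3]) > 0 else None,
            alleles=(r[4], r[5]),
        )
        for r in bim_rows
    ]

    major, minor = (m, n) if mode == 1 else (n, m)
    stride = (minor + 3) // 4
    payload = np.frombuffer(buf, dtype=np.uint8, offset=3)
    if payload.size != major * stride:
        raise GenotypeParseError(
            f"{prefix}.bed: payload of {payload.size} bytes does not match "
            f"{n} samples x {m} variants"
        )
    blocks = payload.reshape(major, stride)
    codes = np.stack(
        [(blocks >> (2 * k)) & 0b11 for k in range(4)], axis=2
    ).reshape(major, 4 * stride)[:, :minor]
    if mode == 1:  # variant-major: rows are variants
        codes = codes.T
    grid = _BED_CODE_TO_PAIR[codes]  # (n, m, 2)

    pheno: dict[str, str] = {}
    for sid, row in zip(sample_ids, fam_rows):
        tok = row[5] if len(row) > 5 else "0"
        pheno[sid] = {"2": CASE, "1": CONTROL}.get(tok, UNKNOWN)
    n_unknown = sum(1 for v in pheno.values() if v == UNKNOWN)
    if n_unknown:
        logger.info("%s.fam: %d samples with unknown phenotype", prefix, n_unknown)
    return GenotypeMatrix(sample_ids, variants, grid), PhenotypeTable(pheno)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(
    path,
    *,
    case_tokens=("case", "2"),
    control_tokens=("control", "1"),
    delimiter: str | None = None,
) -> PhenotypeTable:
    """Read a two-column ``sample_id, status`` file.

    Status tokens are configurable; defaults accept both word coding
    (case/control) and PLINK-style numeric coding (2/1).
    """
    case_set = {t.lower() for t in case_tokens}
    control_set = {t.lower() for t in control_tokens}
    status: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        cells = _split_line(ln, delimiter if delimiter is not None else _sniff_delimiter(ln))
        if len(cells) < 2:
            raise GenotypeParseError(f"{path}: malformed phenotype line {ln!r}")
        sid, tok = cells[0], cells[1].lower()
        if tok in case_set:
            val = CASE
        elif tok in control_set:
            val = CONTROL
        else:
            raise GenotypeParseError(f"{path}: unknown status token {cells[1]!r}")
        if sid in status and status[sid] != val:
            raise GenotypeParseError(
                f"{path}: sample {sid!r} listed with conflicting statuses"
            )
        status[sid] = val
    return PhenotypeTable(status)


def concat_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices over the same variants (allele tables are remapped
    through allele strings, so the inputs need not share index coding)."""
    if a.variant_ids != b.variant_ids:
        raise ValueError("matrices must cover the same variants in the same order")
    tables = [list(v.alleles) for v in a.variants]
    remapped = b.allele_idx.copy()
    for j, (va, vb) in enumerate(zip(a.variants, b.variants)):
        if vb.alleles == va.alleles:
            continue
        lut = np.full(max(len(vb.alleles), 1), MISSING, dtype=np.int16)
        for k, sym in enumerate(vb.alleles):
            if sym not in tables[j]:
                tables[j].append(sym)
            lut[k] = tables[j].index(sym)
        col = remapped[:, j, :]
        called = col[:, 0] >= 0
        col[called] = np.sort(lut[col[called]], axis=1)
    variants = [
        VariantRecord(v.variant_id, v.chromosome, v.position, tuple(tables[j]))
        for j, v in enumerate(a.variants)
    ]
    return GenotypeMatrix(
        list(a.sample_ids) + list(b.sample_ids),
        variants,
        np.concatenate([a.allele_idx, remapped], axis=0),
    )
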