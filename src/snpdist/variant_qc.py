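"""Variant-level quality control and MAF classification.

Variants are screened on call rate, observed allele number, and deviation from
Hardy–Weinberg equilibrium (exact conditional test), then stratified by minor
allele frequency into ``common`` (MAF >= 5%), ``low_frequency``
(0.5% <= MAF < 5%) and ``rare`` (MAF < 0.5%) classes.  The three classes
partition the QC-passing variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp

from .genotype_io import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

COMMON = "common"
LOW_FREQUENCY = "low_frequency"
RARE = "rare"
CLASS_LABELS = (COMMON, LOW_FREQUENCY, RARE)

CONTROLS_ONLY = "controls_only"
ALL_SAMPLES = "all"


@dataclass(frozen=True)
class QcThresholds:
    """Filter cutoffs and MAF class boundaries.

    Defaults are field-standard: call rate >= 0.95, exact HWE P >= 1e-6
    evaluated in controls only, biallelic sites only.  Class boundaries follow
    the usual definitions (rare < 0.5% <= low-frequency < 5% <= common).
    """

    min_call_rate: float = 0.95
    hwe_alpha: float = 1e-6
    hwe_sample_set: str = CONTROLS_ONLY
    low_freq_bound: float = 0.005
    common_bound: float = 0.05
    drop_monomorphic: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.low_freq_bound < self.common_bound < 0.5):
            raise ValueError("need 0 < low_freq_bound < common_bound < 0.5")
        if self.hwe_sample_set not in (CONTROLS_ONLY, ALL_SAMPLES):
            raise ValueError(f"unknown hwe_sample_set {self.hwe_sample_set!r}")


@dataclass
class VariantClassification:
    variant_id: str
    maf: float
    n_called_alleles: int
    class_label: str | None
    qc_pass: bool
    qc_fail_reasons: list[str] = field(default_factory=list)


def _allele_counts(matrix: GenotypeMatrix, j: int) -> np.ndarray:
    idx = matrix.allele_idx[:, j, :]
    vals = idx[idx[:, 0] >= 0].ravel()
    if vals.size == 0:
        return np.zeros(0, dtype=np.int64)
    return np.bincount(vals, minlength=len(matrix.variants[j].alleles))


def compute_maf(matrix: GenotypeMatrix, variant: int | str) -> float:
    """Minor allele frequency at one variant, cases and controls pooled.

    Counts both alleles of every non-missing call; the MAF is the smallest
    observed allele frequency.  A monomorphic site has MAF 0.
    """
    j = matrix.variant_ids.index(variant) if isinstance(variant, str) else variant
    counts = _allele_counts(matrix, j)
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"{matrix.variants[j].variant_id}: all calls missing, MAF undefined"
        )
    observed = counts[counts > 0]
    if observed.size <= 1:
        return 0.0
    return float(observed.min() / total)


def compute_mafs(matrix: GenotypeMatrix) -> np.ndarray:
    """Vectorised per-variant MAF; NaN where every call is missing."""
    idx = matrix.allele_idx
    called = idx[:, :, 0] >= 0
    n_called = called.sum(axis=0) * 2
    max_idx = int(idx.max(initial=0))
    counts = np.zeros((max_idx + 1, matrix.n_variants), dtype=np.int64)
    for a in range(max_idx + 1):
        counts[a] = (idx == a).sum(axis=(0, 2))
    out = np.full(matrix.n_variants, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / np.maximum(n_called, 1)
    for j in range(matrix.n_variants):
        if n_called[j] == 0:
            continue
        nz = freqs[:, j][counts[:, j] > 0]
        out[j] = 0.0 if nz.size <= 1 else nz.min()
    return out


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

# exact integer arithmetic below this many alleles; log-space above
_EXACT_ALLELE_LIMIT = 20_000


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg P-value for one biallelic variant.

    Conditions on the observed allele counts, enumerates every heterozygote
    count of matching parity, and sums the probabilities of all genotype
    tables no more probable than the observed one.  Exact integer arithmetic
    is used for cohort-scale inputs, so ties are resolved exactly.
    """
    for name, v in (("n_AA", n_AA), ("n_Aa", n_Aa), ("n_aa", n_aa)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    hets = range(rare % 2, rare + 1, 2)

    if 2 * n <= _EXACT_ALLELE_LIMIT:
        # ways(h): choose h heterozygotes, then the rare-allele homozygotes,
        # with 2^h orderings of each het's alleles
        ways = [
            math.comb(n, h) * math.comb(n - h, (rare - h) // 2) * (1 << h)
            for h in hets
        ]
        w_obs = ways[(n_Aa - rare % 2) // 2]
        p = sum(w for w in ways if w <= w_obs) / sum(ways)
        return min(1.0, p)

    hs = np.arange(rare % 2, rare + 1, 2, dtype=np.float64)
    homr = (rare - hs) / 2
    homc = n - hs - homr
    logw = (
        gammaln(n + 1)
        - gammaln(hs + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hs * math.log(2.0)
    )
    logw -= logsumexp(logw)
    obs = logw[int((n_Aa - rare % 2) // 2)]
    p = float(np.exp(logw[logw <= obs + 1e-10]).sum())
    return min(1.0, p)


def _biallelic_genotype_counts(
    matrix: GenotypeMatrix, j: int, sample_rows: np.ndarray | None
) -> tuple[int, int, int]:
    col = matrix.allele_idx[:, j, :]
    if sample_rows is not None:
        col = col[sample_rows]
    called = col[col[:, 0] >= 0]
    dosage = called.sum(axis=1)  # count of allele index 1
    n_het = int((dosage == 1).sum())
    return int((dosage == 0).sum()), n_het, int((dosage == 2).sum())


# ---------------------------------------------------------------------------
# QC filter + classification
# ---------------------------------------------------------------------------


def classify_maf(maf: float, thresholds: QcThresholds = QcThresholds()) -> str:
    """Map one MAF to its class label (boundaries: common >= 5%, rare < 0.5%)."""
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    if maf < thresholds.low_freq_bound:
        return RARE
    if maf < thresholds.common_bound:
        return LOW_FREQUENCY
    return COMMON


def classify_by_maf(
    variant_ids,
    mafs,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[list[str], dict[str, set]]:
    """Classify variants by MAF; returns labels plus per-class id sets that
    partition the input."""
    labels = [classify_maf(float(m), thresholds) for m in mafs]
    sets: dict[str, set] = {c: set() for c in CLASS_LABELS}
    for vid, lab in zip(variant_ids, labels):
        sets[lab].add(vid)
    return labels, sets


def apply_qc(
    matrix: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    phenotypes: PhenotypeTable | None = None,
) -> tuple[GenotypeMatrix, list[VariantClassification]]:
    """Filter variants on call rate, allele number and HWE; classify survivors.

    Returns the filtered matrix (variant order preserved) and one
    :class:`VariantClassification` per *input* variant, so every removal is
    accounted for.  HWE is evaluated on controls only when phenotypes are
    supplied and ``thresholds.hwe_sample_set`` says so; otherwise on all
    samples.  Monomorphic variants are retained by default (they are inert in
    every distance) and classified rare.
    """
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise ValueError("cannot QC an empty genotype matrix")

    hwe_rows: np.ndarray | None = None
    if thresholds.hwe_sample_set == CONTROLS_ONLY and phenotypes is not None:
        controls = set(phenotypes.controls)
        hwe_rows = np.array([s in controls for s in matrix.sample_ids])
        if not hwe_rows.any():
            logger.warning("no controls available for HWE; using all samples")
            hwe_rows = None
    elif thresholds.hwe_sample_set == CONTROLS_ONLY:
        logger.info("no phenotypes supplied; HWE computed on all samples")

    call_rates = matrix.call_rates()
    mafs = compute_mafs(matrix)
    classifications: list[VariantClassification] = []
    keep: list[int] = []
    removal_tally: dict[str, int] = {}
    n_monomorphic = 0

    for j, v in enumerate(matrix.variants):
        reasons: list[str] = []
        counts = _allele_counts(matrix, j)
        n_called_alleles = int(counts.sum())
        n_observed_alleles = int((counts > 0).sum())

        if call_rates[j] < thresholds.min_call_rate:
            reasons.append("call_rate")
        if n_observed_alleles > 2:
            reasons.append("multiallelic")
        monomorphic = n_observed_alleles <= 1
        if monomorphic:
            n_monomorphic += 1
            if thresholds.drop_monomorphic:
                reasons.append("monomorphic")
        elif n_observed_alleles == 2 and n_called_alleles > 0:
            # HWE needs counts relative to the two observed alleles; allele
            # index coding is biallelic here only when max index <= 1
            if int(matrix.allele_idx[:, j, :].max()) <= 1:
                hom0, het, hom1 = _biallelic_genotype_counts(matrix, j, hwe_rows)
                if hom0 + het + hom1 > 0:
                    if hwe_exact_test(hom0, het, hom1) < thresholds.hwe_alpha:
                        reasons.append("hwe")

        maf = float(mafs[j]) if np.isfinite(mafs[j]) else float("nan")
        label = classify_maf(maf, thresholds) if np.isfinite(mafs[j]) else None
        ok = not reasons
        classifications.append(
            VariantClassification(
                v.variant_id, maf, n_called_alleles, label, ok, reasons
            )
        )
        if ok:
            keep.append(j)
        else:
            for r in reasons:
                removal_tally[r] = removal_tally.get(r, 0) + 1

    if n_monomorphic:
        logger.info("%d monomorphic variants (classified rare)", n_monomorphic)
    for reason, count in sorted(removal_tally.items()):
        logger.info("QC removed %d variants: %s", count, reason)
    if not keep:
        logger.warning("QC removed every variant")

    filtered = GenotypeMatrix(
        list(matrix.sample_ids),
        [matrix.variants[j] for j in keep],
        matrix.allele_idx[:, keep, :].copy(),
    )
    return filtered, classifications


def class_variant_sets(
    classifications: list[VariantClassification],
) -> dict[str, set]:
    """Per-class id sets over the QC-passing variants (a partition)."""
    sets: dict[str, set] = {c: set() for c in CLASS_LABELS}
    for c in classifications:
        if c.qc_pass and c.class_label is not None:
            sets[c.class_label].add(c.variant_id)
    return sets


def write_classification_report(
    classifications: list[VariantClassification], path, *, delimiter: str = "\t"
) -> None:
    lines = [delimiter.join(["variant_id", "maf", "class", "qc_pass", "fail_reasons"])]
    for c in classifications:
        lines.append(
            delimiter.join(
                [
                    c.variant_id,
                    "NA" if math.isnan(c.maf) else f"{c.maf:.6g}",
                    c.class_label or "NA",
                    str(c.qc_pass).lower(),
                    ",".join(c.qc_fail_reasons) or "-",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
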