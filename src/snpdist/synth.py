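"""Synthetic diploid case-control cohorts with class-specific divergence.

The generator emulates the study design the toolkit targets: an exome-chip
style variant panel dominated by rare sites, a case and a control group drawn
in Hardy–Weinberg proportions within each group, and a disease signal
expressed as allele-frequency divergence between the case and control pools,
concentrated in a chosen variant class (by default the rare class, mirroring
the premise that most functional variation in such cohorts is rare).

The divergence follows the Balding–Nichols model: each affected variant has
an ancestral minor-allele frequency ``q`` drawn inside its class band, and
the case and control groups each realise a frequency drawn from a Beta
distribution with mean ``q`` and variance ``fst * q * (1 - q)``.  Displacing
*both* groups from the shared ancestral frequency keeps their heterozygosity
exchangeable; a one-sided shift (only cases displaced) makes within-group
distances systematically asymmetric, and after the pooled-MAF classifier
selects which variants count as rare, the case/control contrast then lands
on negative eigenvalues that classical scaling discards — a degenerate
geometry no diverged pair of populations shows.

A variant's class band constrains its *cohort-pooled* population frequency —
the same quantity the QC classifier estimates — so for affected variants the
frequency pair is redrawn until the pooled mean lies inside the band.  A
variant designed rare therefore stays rare in expectation rather than
migrating into the low-frequency stratum when one group's frequency drifts
high.  Variants are independent — no linkage disequilibrium — and
missingness is independent per call.

Every cohort ships with a truth table of the planted per-variant frequencies
so tests can condition on which variants actually carry an effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (
    CASE,
    CONTROL,
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    VariantRecord,
)
from .variant_qc import COMMON, LOW_FREQUENCY, RARE

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    Ancestral minor-allele frequencies are drawn uniformly within each
    class's band; ``affected_fraction[class]`` of that class's variants get
    Balding–Nichols case/control divergence of magnitude ``fst`` (see module
    docstring), conditioned on the pooled frequency staying in the band; the
    rest are frequency-identical between groups.  The default ``fst`` of
    0.02 was set by a design power analysis: it places the planted
    rare-class divergence comfortably inside the regime the
    distance/MDS/T² pipeline detects at the default cohort size.  The rare
    band's floor of 5e-4 keeps expected minor-allele counts at or above one
    at the default cohort size, so empirical classification is stable.
    """

    n_cases: int = 200
    n_controls: int = 200
    n_common: int = 2000
    n_low_freq: int = 2000
    n_rare: int = 5000
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    low_freq_maf_range: tuple[float, float] = (0.005, 0.05)
    rare_maf_range: tuple[float, float] = (0.0005, 0.005)
    affected_fraction: dict = field(
        default_factory=lambda: {COMMON: 0.0, LOW_FREQUENCY: 0.0, RARE: 1.0}
    )
    fst: float = 0.02
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_common", "n_low_freq", "n_rare"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("missing_rate",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for cls, frac in self.affected_fraction.items():
            if cls not in (COMMON, LOW_FREQUENCY, RARE):
                raise ValueError(f"unknown class {cls!r} in affected_fraction")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("affected fractions must lie in [0, 1]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[GenotypeMatrix, PhenotypeTable, pd.DataFrame]:
    """Draw a reproducible case-control cohort from ``spec``.

    Returns the genotype matrix (cases first), the phenotype table, and a
    truth table with one row per variant: design class, ancestral frequency,
    realised case and control minor-allele frequencies, and whether the
    variant carries planted divergence.  Genotypes are two independent
    allele draws per individual at the group's frequency (HWE within group);
    the same seed reproduces the cohort bit for bit.
    """
    n = spec.n_cases + spec.n_controls
    if n == 0:
        raise ValueError("cohort needs at least one sample")
    rng = np.random.default_rng(spec.seed)

    blocks = [
        (COMMON, spec.n_common, spec.common_maf_range),
        (LOW_FREQUENCY, spec.n_low_freq, spec.low_freq_maf_range),
        (RARE, spec.n_rare, spec.rare_maf_range),
    ]
    classes: list[str] = []
    anc_freq_parts = []
    affected_parts = []
    bands: list[tuple[float, float]] = []
    for label, count, (lo, hi) in blocks:
        classes.extend([label] * count)
        bands.extend([(lo, hi)] * count)
        anc_freq_parts.append(rng.uniform(lo, hi, size=count))
        frac = spec.affected_fraction.get(label, 0.0)
        affected_parts.append(rng.random(count) < frac)
    anc_freq = np.concatenate(anc_freq_parts) if classes else np.empty(0)
    affected = np.concatenate(affected_parts) if classes else np.empty(0, dtype=bool)
    m = len(classes)

    case_freq = anc_freq.copy()
    ctrl_freq = anc_freq.copy()
    if spec.fst > 0 and affected.any():
        # Balding–Nichols: Beta with mean q and variance fst * q * (1 - q),
        # redrawn until the pooled frequency stays inside the class band
        idx = np.flatnonzero(affected)
        q = anc_freq[idx]
        lo = np.array([bands[i][0] for i in idx])
        hi = np.array([bands[i][1] for i in idx])
        shape = (1.0 - spec.fst) / spec.fst
        p_case = rng.beta(q * shape, (1.0 - q) * shape)
        p_ctrl = rng.beta(q * shape, (1.0 - q) * shape)
        for _ in range(1000):
            pooled = (p_case + p_ctrl) / 2.0
            bad = (pooled < lo) | (pooled >= hi)
            if not bad.any():
                break
            p_case[bad] = rng.beta(q[bad] * shape, (1.0 - q[bad]) * shape)
            p_ctrl[bad] = rng.beta(q[bad] * shape, (1.0 - q[bad]) * shape)
        else:  # pragma: no cover - only reachable with extreme fst
            raise RuntimeError("could not realise in-band divergent frequencies")
        case_freq[idx] = p_case
        ctrl_freq[idx] = p_ctrl

    # two independent allele draws per individual => dosage ~ Binomial(2, p)
    dos_case = rng.binomial(2, case_freq, size=(spec.n_cases, m))
    dos_ctrl = rng.binomial(2, ctrl_freq, size=(spec.n_controls, m))
    dosage = np.concatenate([dos_case, dos_ctrl], axis=0).astype(np.int16)
    grid = np.empty((n, m, 2), dtype=np.int16)
    grid[:, :, 0] = dosage > 1  # sorted pair: (0,0) / (0,1) / (1,1)
    grid[:, :, 1] = dosage > 0
    if spec.missing_rate > 0:
        drop = rng.random((n, m)) < spec.missing_rate
        grid[drop] = MISSING

    ref = rng.integers(0, 4, size=m)
    alt = (ref + rng.integers(1, 4, size=m)) % 4
    width = max(len(str(max(m, 1))), 4)
    variants = [
        VariantRecord(
            f"{classes[j]}_{j:0{width}d}",
            chromosome="1",
            position=j + 1,
            alleles=(str(_NUCLEOTIDES[ref[j]]), str(_NUCLEOTIDES[alt[j]])),
        )
        for j in range(m)
    ]
    sample_ids = [f"case_{i:04d}" for i in range(spec.n_cases)] + [
        f"ctrl_{i:04d}" for i in range(spec.n_controls)
    ]
    matrix = GenotypeMatrix(sample_ids, variants, grid)
    phenotypes = PhenotypeTable(
        {s: (CASE if s.startswith("case_") else CONTROL) for s in sample_ids}
    )
    truth = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "design_class": classes,
            "ancestral_freq": anc_freq,
            "control_freq": ctrl_freq,
            "case_freq": case_freq,
            "affected": affected,
        }
    )
    return matrix, phenotypes, truth


def worked_example_fixture() -> GenotypeMatrix:
    """The three-subject, eight-SNP worked example used throughout the docs.

    Subjects X, Y, Z with pairwise genotype Hamming distances 7 (X,Y),
    3 (Y,Z) and 5 (X,Z); no missing calls.
    """
    annot = ["A/T", "G/T", "C/G", "C/T", "C/T", "A/G", "A/C", "C/T"]
    genotypes = {
        "X": ["AT", "GG", "CG", "CC", "CC", "AG", "AC", "TT"],
        "Y": ["AA", "GG", "CC", "TT", "CT", "GG", "CC", "CT"],
        "Z": ["AA", "GG", "CC", "CC", "CT", "AA", "CC", "TT"],
    }
    variants = [
        VariantRecord(f"SNP{j + 1}", alleles=tuple(annot[j].split("/")))
        for j in range(8)
    ]
    grid = np.empty((3, 8, 2), dtype=np.int16)
    for i, sid in enumerate(genotypes):
        for j, gt in enumerate(genotypes[sid]):
            table = variants[j].alleles
            pair = sorted(table.index(sym) for sym in gt)
            grid[i, j] = pair
    return GenotypeMatrix(list(genotypes), variants, grid)
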