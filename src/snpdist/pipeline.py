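"""End-to-end orchestration: load -> QC -> classify -> distance -> MDS -> T².

The main entry points are :func:`run_analysis` (Hamming or normalised-Hamming
distances, one MDS plane and one Hotelling T² per requested variant class)
and :func:`run_stratification_check` (the same flow on the IBS allele-sharing
distance, with MAD-based outlier flagging, the conventional screen for
population stratification).

Runs are deterministic given the same configuration and inputs, and every
per-class artifact (distance matrix, coordinates, eigenvalues, figures) can
be written to an output directory alongside a consolidated text + JSON
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .genotype_io import (
    CASE,
    CONTROL,
    GenotypeMatrix,
    PhenotypeTable,
    read_genotype_table,
    read_phenotypes,
    read_plink_binary,
    read_vcf,
)
from .variant_qc import (
    CLASS_LABELS,
    QcThresholds,
    apply_qc,
    class_variant_sets,
    write_classification_report,
)
from .distance import (
    HAMMING,
    IBS,
    DistanceMatrix,
    pairwise_distances,
    write_distance_matrix,
)
from .ordination import (
    MDSResult,
    classical_mds,
    plot_embedding,
    write_coordinates,
    write_eigenvalues,
)
from .stats import HotellingResult, separation_report

logger = logging.getLogger(__name__)

ALL = "all"
VARIANT_SETS = (ALL,) + CLASS_LABELS


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    ``genotypes`` / ``phenotypes`` may be file paths (with ``format`` one of
    ``table`` / ``vcf`` / ``plink``) or already-loaded objects, which is how
    the synthetic subcommand and the test-suite drive the pipeline.
    """

    genotypes: object = None  # path or GenotypeMatrix
    phenotypes: object = None  # path or PhenotypeTable
    format: str = "table"
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    metric: str = HAMMING
    classes: tuple = VARIANT_SETS
    mds_dims: int = 2
    out_dir: str | None = None
    seed: int = 0
    make_plots: bool = False
    outlier_mad_multiplier: float = 6.0
    exclude_outliers: bool = False

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(VARIANT_SETS)
        if bad:
            raise ValueError(f"unknown variant classes requested: {sorted(bad)}")


@dataclass
class ClassResult:
    """Per-variant-class results bundle inside a :class:`RunReport`."""

    variant_class: str
    n_variants: int
    metric: str
    distance_mean: float
    distance_max: float
    eigenvalues_head: list
    negative_eigenvalue_mass: float
    hotelling: HotellingResult | None
    hotelling_error: str | None
    p_bonferroni: float | None = None
    outliers: list = field(default_factory=list)


@dataclass
class RunReport:
    n_samples: int
    n_cases: int
    n_controls: int
    n_variants_input: int
    n_variants_pass: int
    qc_removals: dict
    class_counts: dict
    results: dict  # class label -> ClassResult
    package_version: str = __version__
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = asdict(self)
        return out

    def to_text(self) -> str:
        lines = [
            f"snpdist {self.package_version}",
            f"samples: {self.n_samples} ({self.n_cases} cases, "
            f"{self.n_controls} controls)",
            f"variants: {self.n_variants_input} input, "
            f"{self.n_variants_pass} pass QC "
            f"(removed: {self.qc_removals or 'none'})",
            "class counts: "
            + ", ".join(f"{k}={v}" for k, v in self.class_counts.items()),
            "",
        ]
        for label, r in self.results.items():
            lines.append(f"[{label}] {r.n_variants} variants, metric {r.metric}")
            lines.append(
                f"  distance mean {r.distance_mean:.4g}, max {r.distance_max:.4g}; "
                f"negative eigenvalue mass {r.negative_eigenvalue_mass:.3g}"
            )
            if r.hotelling is not None:
                h = r.hotelling
                extra = (
                    f", Bonferroni P {min(1.0, r.p_bonferroni):.4g}"
                    if r.p_bonferroni is not None
                    else ""
                )
                lines.append(f"  {h}{extra}")
            else:
                lines.append(f"  Hotelling T2 unavailable: {r.hotelling_error}")
            if r.outliers:
                lines.append(f"  outliers flagged: {', '.join(r.outliers)}")
            lines.append("")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _load_genotypes(config: RunConfig) -> tuple[GenotypeMatrix, PhenotypeTable | None]:
    g = config.genotypes
    if isinstance(g, GenotypeMatrix):
        return g, None
    if g is None:
        raise ValueError("no genotypes supplied")
    path = Path(g)
    if config.format == "table":
        return read_genotype_table(path), None
    if config.format == "vcf":
        return read_vcf(path), None
    if config.format == "plink":
        return read_plink_binary(path)
    raise ValueError(f"unknown genotype format {config.format!r}")


def _load_phenotypes(config: RunConfig, fallback: PhenotypeTable | None) -> PhenotypeTable:
    p = config.phenotypes
    if isinstance(p, PhenotypeTable):
        return p
    if p is not None:
        return read_phenotypes(p)
    if fallback is not None:
        return fallback
    raise ValueError("no phenotypes supplied")


def _align(
    matrix: GenotypeMatrix, phenotypes: PhenotypeTable
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Intersect genotype and phenotype samples, dropping unknown statuses."""
    usable = [
        s
        for s in matrix.sample_ids
        if s in phenotypes and phenotypes[s] in (CASE, CONTROL)
    ]
    n_geno_only = matrix.n_samples - len(usable)
    n_pheno_only = len(phenotypes) - len(usable)
    if not usable:
        raise ValueError("no overlap between genotype samples and phenotype table")
    if n_geno_only or n_pheno_only:
        logger.info(
            "sample alignment: %d analyzed; %d genotyped samples dropped "
            "(missing/unknown phenotype), %d phenotyped samples absent from "
            "genotypes",
            len(usable),
            n_geno_only,
            max(n_pheno_only, 0),
        )
    sub = matrix.subset_samples(usable) if n_geno_only else matrix
    return sub, PhenotypeTable({s: phenotypes[s] for s in usable})


def flag_mds_outliers(
    mds: MDSResult, multiplier: float = 6.0, dims: int = 2
) -> list[str]:
    """Samples farther than ``multiplier`` scaled MADs from the coordinate-wise
    median in any of the first ``dims`` MDS axes."""
    coords = mds.coordinates[:, : min(dims, mds.coordinates.shape[1])]
    if coords.size == 0:
        return []
    med = np.median(coords, axis=0)
    mad = 1.4826 * np.median(np.abs(coords - med), axis=0)
    dev = np.abs(coords - med)
    flagged = ((dev > multiplier * mad[None, :]) & (mad[None, :] > 0)).any(axis=1)
    return [s for s, f in zip(mds.sample_ids, flagged) if f]


def _analyze_class(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    label: str,
    variant_ids,
    config: RunConfig,
    out_dir: Path | None,
    flag_outliers: bool,
) -> ClassResult:
    dist = pairwise_distances(
        matrix, variant_ids=variant_ids, metric=config.metric, variant_set_label=label
    )
    k = min(config.mds_dims, dist.n_samples - 1)
    mds = classical_mds(dist, k=k)

    outliers: list[str] = []
    if flag_outliers:
        outliers = flag_mds_outliers(mds, config.outlier_mad_multiplier)
        if outliers:
            logger.warning("[%s] %d outlier samples flagged: %s",
                           label, len(outliers), ", ".join(outliers[:10]))
        if config.exclude_outliers and outliers:
            keep = [s for s in mds.sample_ids if s not in set(outliers)]
            logger.info("[%s] re-embedding without %d outliers", label, len(outliers))
            mds = classical_mds(dist.submatrix(keep), k=min(k, len(keep) - 1))

    hotelling: HotellingResult | None = None
    error: str | None = None
    try:
        pheno_sub = PhenotypeTable(
            {s: phenotypes[s] for s in mds.sample_ids if s in phenotypes}
        )
        hotelling = separation_report(mds, pheno_sub, dims=config.mds_dims)
    except (ValueError, np.linalg.LinAlgError) as exc:
        error = str(exc)
        logger.warning("[%s] Hotelling T2 unavailable: %s", label, error)

    if out_dir is not None:
        write_distance_matrix(dist, out_dir / f"distance_{label}.csv")
        write_coordinates(mds, out_dir / f"mds_coordinates_{label}.csv")
        write_eigenvalues(mds, out_dir / f"mds_eigenvalues_{label}.csv")
        if config.make_plots:
            plot_embedding(
                mds, phenotypes, out_dir / f"mds_{label}.png",
                title=f"{label} ({dist.n_variants_used} variants, {config.metric})",
            )

    off = dist.values[np.triu_indices(dist.n_samples, k=1)]
    return ClassResult(
        variant_class=label,
        n_variants=dist.n_variants_used,
        metric=config.metric,
        distance_mean=float(off.mean()) if off.size else 0.0,
        distance_max=float(off.max()) if off.size else 0.0,
        eigenvalues_head=[float(v) for v in mds.eigenvalues[:5]],
        negative_eigenvalue_mass=mds.negative_eigenvalue_mass,
        hotelling=hotelling,
        hotelling_error=error,
        outliers=outliers,
    )


def _run(config: RunConfig, flag_outliers: bool) -> RunReport:
    matrix, fam_pheno = _load_genotypes(config)
    phenotypes = _load_phenotypes(config, fam_pheno)
    matrix, phenotypes = _align(matrix, phenotypes)

    filtered, classifications = apply_qc(matrix, config.thresholds, phenotypes)
    sets = class_variant_sets(classifications)
    removals: dict[str, int] = {}
    for c in classifications:
        for r in c.qc_fail_reasons:
            removals[r] = removals.get(r, 0) + 1
    class_counts = {k: len(v) for k, v in sets.items()}

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_classification_report(classifications, out_dir / "variant_qc.tsv")

    results: dict[str, ClassResult] = {}
    n_tested = 0
    for label in config.classes:
        ids = None if label == ALL else sorted(sets[label])
        if label != ALL and not ids:
            logger.warning("class %r has no variants after QC; skipped", label)
            continue
        results[label] = _analyze_class(
            filtered, phenotypes, label, ids, config, out_dir, flag_outliers
        )
        if results[label].hotelling is not None:
            n_tested += 1
    for r in results.values():
        if r.hotelling is not None and n_tested:
            r.p_bonferroni = min(1.0, r.hotelling.p_value * n_tested)

    cfg = {
        "metric": config.metric,
        "classes": list(config.classes),
        "mds_dims": config.mds_dims,
        "min_call_rate": config.thresholds.min_call_rate,
        "hwe_alpha": config.thresholds.hwe_alpha,
        "hwe_sample_set": config.thresholds.hwe_sample_set,
        "seed": config.seed,
    }
    report = RunReport(
        n_samples=matrix.n_samples,
        n_cases=len(phenotypes.cases),
        n_controls=len(phenotypes.controls),
        n_variants_input=matrix.n_variants,
        n_variants_pass=filtered.n_variants,
        qc_removals=removals,
        class_counts=class_counts,
        results=results,
        config=cfg,
    )
    if out_dir is not None:
        (out_dir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=str) + "\n"
        )
        (out_dir / "report.txt").write_text(report.to_text())
    return report


def run_analysis(config: RunConfig) -> RunReport:
    """Full case-control analysis: QC, MAF classes, per-class distance ->
    MDS -> Hotelling T² (Bonferroni-adjusted P reported alongside the raw
    values)."""
    return _run(config, flag_outliers=False)


def run_stratification_check(config: RunConfig) -> RunReport:
    """IBS-distance MDS stratification screen with MAD outlier flagging.

    Identical flow to :func:`run_analysis` but the metric is forced to the
    allele-sharing IBS distance.  Flagging is reporting-only unless
    ``config.exclude_outliers`` is set.
    """
    cfg = RunConfig(**{**asdict_shallow(config), "metric": IBS})
    return _run(cfg, flag_outliers=True)


def asdict_shallow(config: RunConfig) -> dict:
    # dataclasses.asdict would deep-copy the genotype matrix; keep references
    return {f: getattr(config, f) for f in config.__dataclass_fields__}
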