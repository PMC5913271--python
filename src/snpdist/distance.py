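"""Pairwise genotype distances between individuals.

Three metrics over a chosen variant set:

* ``hamming`` — the count of variant positions at which two individuals'
  unordered diploid genotypes differ (a whole-genotype 0/1 mismatch, no
  partial credit for sharing one allele);
* ``normalized_hamming`` — the same count divided by the number of positions
  compared, so it lies in [0, 1];
* ``ibs`` — allele-sharing distance ``1 - (IBS2 + 0.5*IBS1) / compared``,
  the metric population-stratification checks conventionally use.

Missing data follow pairwise-complete deletion: a position where either call
is missing contributes neither to the mismatch count nor to the denominator,
which reduces exactly to the complete-data definitions when nothing is
missing.

The matrix builder :func:`pairwise_distances` avoids the quadratic
pair-by-pair loop: per-site genotype categories are one-hot encoded and the
match/compared counts for all pairs are accumulated with BLAS matrix
products, which makes cohort-scale (hundreds of samples, tens of thousands of
variants) matrices cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

HAMMING = "hamming"
NORMALIZED_HAMMING = "normalized_hamming"
IBS = "ibs"
METRICS = (HAMMING, NORMALIZED_HAMMING, IBS)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample-by-sample distance with bookkeeping.

    ``compared`` holds, for each pair, the number of positions at which both
    calls were non-missing (``None`` for matrices that did not arise from
    genotypes, e.g. MDS reconstructions).
    """

    sample_ids: list[str]
    values: np.ndarray
    metric: str
    variant_set_label: str = "custom"
    n_variants_used: int = 0
    compared: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"distance grid must be {n}x{n}")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(
            list(sample_ids),
            self.values[np.ix_(idx, idx)].copy(),
            self.metric,
            self.variant_set_label,
            self.n_variants_used,
            None if self.compared is None else self.compared[np.ix_(idx, idx)].copy(),
        )


# ---------------------------------------------------------------------------
# per-pair operations (also serve as the reference semantics)
# ---------------------------------------------------------------------------


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(
            f"genotype vectors must share an (n_variants, 2) shape, "
            f"got {x.shape} and {y.shape}"
        )
    return x, y


def hamming_distance(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Genotype mismatch count between two aligned genotype vectors.

    Returns ``(count, compared)``: the number of both-called positions where
    the unordered allele pairs differ, and the number of both-called
    positions.
    """
    x, y = _check_pair(x, y)
    both = (x[:, 0] >= 0) & (y[:, 0] >= 0)
    same = (x[:, 0] == y[:, 0]) & (x[:, 1] == y[:, 1])
    return int((both & ~same).sum()), int(both.sum())


def normalized_hamming(x: np.ndarray, y: np.ndarray) -> float:
    """Mismatch count over compared positions; equals H/n on complete data."""
    count, compared = hamming_distance(x, y)
    if compared == 0:
        raise ValueError("no positions with both calls present; distance undefined")
    return count / compared


def ibs_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Allele-sharing (identity-by-state) distance between two individuals.

    Each both-called site is IBS2 (identical unordered pair), IBS1 (exactly
    one allele shared counting multiplicity) or IBS0; the distance is
    ``1 - (IBS2 + 0.5*IBS1) / compared``.
    """
    x, y = _check_pair(x, y)
    both = (x[:, 0] >= 0) & (y[:, 0] >= 0)
    compared = int(both.sum())
    if compared == 0:
        raise ValueError("no positions with both calls present; distance undefined")
    xs, ys = x[both], y[both]
    ibs2 = (xs[:, 0] == ys[:, 0]) & (xs[:, 1] == ys[:, 1])
    share_any = (
        (xs[:, 0:1] == ys[:, 0:2]) | (xs[:, 1:2] == ys[:, 0:2])
    ).any(axis=1)
    ibs1 = share_any & ~ibs2
    score = ibs2.sum() + 0.5 * ibs1.sum()
    return float(1.0 - score / compared)


# ---------------------------------------------------------------------------
# matrix builder
# ---------------------------------------------------------------------------


def _site_category_ranks(idx: np.ndarray) -> tuple[np.ndarray, int]:
    """Dense per-site genotype-category ranks (missing stays -1)."""
    n, m, _ = idx.shape
    base = int(idx.max(initial=0)) + 2  # shift so missing encodes distinctly
    codes = (idx[:, :, 0].astype(np.int32) + 1) * base + (idx[:, :, 1] + 1)
    missing = idx[:, :, 0] < 0
    ranks = np.full((n, m), -1, dtype=np.int16)
    max_cats = 0
    for j in range(m):
        col = codes[:, j]
        called = ~missing[:, j]
        if not called.any():
            continue
        uniq, inv = np.unique(col[called], return_inverse=True)
        ranks[called, j] = inv.astype(np.int16)
        max_cats = max(max_cats, len(uniq))
    return ranks, max_cats


def _pairwise_match_counts(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(matches, compared) integer matrices over all sample pairs."""
    ranks, max_cats = _site_category_ranks(idx)
    called = (ranks >= 0).astype(np.float32)
    compared = called @ called.T
    matches = np.zeros_like(compared)
    for g in range(max_cats):
        a = (ranks == g).astype(np.float32)
        matches += a @ a.T
    return np.rint(matches).astype(np.int64), np.rint(compared).astype(np.int64)


def _pairwise_ibs_scores(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Summed per-site IBS scores (0/1/2) and compared counts for all pairs.

    Uses the identity ``IBS = 2 - 0.5 * sum_a |dosage_i(a) - dosage_j(a)|``
    and decomposes each |dosage difference| into products of dosage-class
    indicators, so everything reduces to matrix products.
    """
    n, m, _ = idx.shape
    called = (idx[:, :, 0] >= 0).astype(np.float32)
    compared = called @ called.T
    max_allele = int(idx.max(initial=0))
    absdiff = np.zeros((n, n), dtype=np.float32)
    for a in range(max_allele + 1):
        dosage = (idx == a).sum(axis=2).astype(np.int8)  # 0, 1 or 2 copies
        d0 = ((dosage == 0) & (called > 0)).astype(np.float32)
        d1 = (dosage == 1).astype(np.float32)
        d2 = (dosage == 2).astype(np.float32)
        upper = d0 @ (d1 + 2.0 * d2).T + d1 @ d2.T
        absdiff += upper + upper.T
    scores = 2.0 * compared - 0.5 * absdiff
    return scores, np.rint(compared).astype(np.int64)


def pairwise_distances(
    matrix: GenotypeMatrix,
    variant_ids=None,
    metric: str = HAMMING,
    variant_set_label: str = "custom",
) -> DistanceMatrix:
    """Distance matrix over every unordered sample pair for a variant subset.

    ``variant_ids=None`` uses every variant (label ``all`` unless overridden).
    The result is independent of traversal order and matches the per-pair
    reference functions exactly.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples for pairwise distances")
    if variant_ids is None:
        sub = matrix
        if variant_set_label == "custom":
            variant_set_label = "all"
    else:
        variant_ids = list(variant_ids)
        if not variant_ids:
            raise ValueError("empty variant subset")
        sub = matrix.subset_variants(variant_ids)
    if sub.n_variants == 0:
        raise ValueError("empty variant subset")

    idx = sub.allele_idx
    if metric == IBS:
        scores, compared = _pairwise_ibs_scores(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = 1.0 - scores / (2.0 * compared)
        values[compared == 0] = np.nan
        np.fill_diagonal(values, 0.0)
        if np.isnan(values).any():
            raise ValueError("some sample pairs share no called positions")
    else:
        matches, compared = _pairwise_match_counts(idx)
        mism = (compared - matches).astype(float)
        if metric == HAMMING:
            values = mism
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                values = mism / compared
            values[compared == 0] = np.nan
            np.fill_diagonal(values, 0.0)
            if np.isnan(values).any():
                raise ValueError("some sample pairs share no called positions")
    values = np.asarray(values, dtype=float)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(compared, 0)
    return DistanceMatrix(
        list(sub.sample_ids),
        values,
        metric,
        variant_set_label,
        sub.n_variants,
        compared,
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def write_distance_matrix(d: DistanceMatrix, path, *, long_format: bool = False) -> None:
    """Write as a square table (header row/column of sample ids) or as a
    long-format ``(id1, id2, distance, compared)`` table."""
    if long_format:
        rows = []
        for i in range(d.n_samples):
            for j in range(i + 1, d.n_samples):
                rows.append(
                    {
                        "id1": d.sample_ids[i],
                        "id2": d.sample_ids[j],
                        "distance": d.values[i, j],
                        "compared": 0 if d.compared is None else int(d.compared[i, j]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    else:
        df = pd.DataFrame(d.values, index=d.sample_ids, columns=d.sample_ids)
        df.to_csv(path, index_label="sample", float_format="%.10g")


def read_distance_matrix(path, metric: str = "hamming") -> DistanceMatrix:
    """Read either serialisation back (the format is sniffed from the header)."""
    head = Path(path).read_text().splitlines()[0]
    if head.startswith("id1,"):
        df = pd.read_csv(path)
        ids = sorted(set(df["id1"]) | set(df["id2"]))
        pos = {s: i for i, s in enumerate(ids)}
        values = np.zeros((len(ids), len(ids)))
        compared = np.zeros((len(ids), len(ids)), dtype=np.int64)
        for row in df.itertuples():
            i, j = pos[row.id1], pos[row.id2]
            values[i, j] = values[j, i] = row.distance
            compared[i, j] = compared[j, i] = row.compared
        return DistanceMatrix(ids, values, metric, compared=compared)
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(), metric)
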