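"""Two-sample Hotelling's T² test of case-control mean separation.

The statistic is the multivariate generalisation of the pooled two-sample t
test: with group means m1, m2 and pooled covariance S (denominator
n1 + n2 - 2),

    T² = (n1 n2 / (n1 + n2)) (m1 - m2)' S⁻¹ (m1 - m2)

and, under multivariate normality with equal covariances,

    F = T² (n1 + n2 - p - 1) / (p (n1 + n2 - 2))  ~  F(p, n1 + n2 - p - 1).

Applied here to the first two MDS coordinates of each individual, it asks
whether cases and controls occupy the same location in the MDS plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .genotype_io import CASE, CONTROL, PhenotypeTable
from .ordination import MDSResult

logger = logging.getLogger(__name__)

#: condition-number ceiling before the pooled covariance is declared singular
_COND_LIMIT = 1e12

#: conventional floor used by statistical software when printing tiny P-values
P_FLOOR = 2.2e-16


@dataclass
class HotellingResult:
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n1: int
    n2: int
    p: int

    def format_p(self) -> str:
        """Human-readable P with the conventional ``< 2.2e-16`` floor."""
        return f"< {P_FLOOR:g}" if self.p_value < P_FLOOR else f"{self.p_value:.4g}"

    def __str__(self) -> str:
        return (
            f"Hotelling T2 = {self.t2:.4g}, F({self.df1}, {self.df2}) = "
            f"{self.f_stat:.4g}, P {self.format_p()} "
            f"(n1={self.n1}, n2={self.n2}, p={self.p})"
        )


def hotelling_two_sample(group1: np.ndarray, group2: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling's T² for equality of mean vectors.

    ``group1``/``group2`` are (n_i, p) coordinate arrays with n_i >= 2 and
    p <= n1 + n2 - 2.  Raises if the pooled covariance is numerically
    singular (condition number above 1e12) rather than pseudo-inverting.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.ndim != 2 or g2.ndim != 2 or g1.shape[1] != g2.shape[1]:
        raise ValueError("groups must be 2-D arrays with a common dimension")
    n1, p = g1.shape
    n2 = g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs at least two members (got n1={n1}, n2={n2})"
        )
    if p < 1 or p > n1 + n2 - 2:
        raise ValueError(f"dimension p={p} must satisfy 1 <= p <= n1 + n2 - 2")

    m1 = g1.mean(axis=0)
    m2 = g2.mean(axis=0)
    c1 = g1 - m1
    c2 = g2 - m2
    pooled = (c1.T @ c1 + c2.T @ c2) / (n1 + n2 - 2)
    if np.linalg.cond(pooled) > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular or near-singular; reduce the tested "
            "dimension (e.g. fewer MDS axes) or drop collinear coordinates"
        )
    diff = m1 - m2
    t2 = float((n1 * n2) / (n1 + n2) * diff @ np.linalg.solve(pooled, diff))
    t2 = max(t2, 0.0)
    df1 = p
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / (df1 * (n1 + n2 - 2))
    p_value = float(sps.f.sf(f_stat, df1, df2))
    return HotellingResult(t2, f_stat, df1, df2, max(p_value, 0.0), n1, n2, p)


def separation_report(
    mds: MDSResult, phenotypes: PhenotypeTable, dims: int = 2
) -> HotellingResult:
    """Hotelling's T² on the leading MDS coordinates, split by case/control.

    Every embedded sample must carry a phenotype and both classes need at
    least two members.  If the embedding holds fewer than ``dims`` axes the
    available ones are used (logged).
    """
    missing = [s for s in mds.sample_ids if s not in phenotypes]
    if missing:
        raise ValueError(f"samples without phenotype: {missing[:5]}")
    avail = mds.coordinates.shape[1]
    if avail < dims:
        logger.warning("embedding has %d axes; testing %d instead of %d",
                       avail, avail, dims)
        dims = avail
    if dims < 1:
        raise ValueError("no coordinates available to test")
    cases = [i for i, s in enumerate(mds.sample_ids) if phenotypes[s] == CASE]
    controls = [i for i, s in enumerate(mds.sample_ids) if phenotypes[s] == CONTROL]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError(
            f"each class needs at least two members "
            f"(n_case={len(cases)}, n_control={len(controls)})"
        )
    logger.info("Hotelling T2 on %d cases vs %d controls in %d dimensions",
                len(cases), len(controls), dims)
    coords = mds.coordinates[:, :dims]
    return hotelling_two_sample(coords[cases], coords[controls])
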