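"""Classical (Torgerson) multidimensional scaling of a distance matrix.

Given pairwise distances ``D``, the doubly centered Gram matrix
``B = -1/2 J D^(2) J`` (``J = I - 11'/n``) is eigendecomposed and the top-k
positive eigenpairs give coordinates ``v_c * sqrt(lambda_c)``.  For a
Euclidean input the embedding reproduces the distances exactly; genotype
Hamming matrices need not be Euclidean, in which case negative eigenvalues
are dropped from the coordinates but kept in the reported spectrum together
with their relative mass.

Everything is deterministic: eigenvalues are sorted descending with the index
as tie-breaker, and each coordinate column is sign-fixed so that its entry of
largest absolute value is positive (first index wins ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import squareform, pdist

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)

_EIG_REL_TOL = 1e-12


@dataclass
class MDSResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # full spectrum, descending
    k: int
    negative_eigenvalue_mass: float

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for c in range(coords.shape[1]):
        col = coords[:, c]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            coords[:, c] = -col
    return coords


def classical_mds(d: DistanceMatrix | np.ndarray, k: int = 2) -> MDSResult:
    """Embed a distance matrix into ``k`` dimensions by classical scaling.

    If fewer than ``k`` positive eigenvalues exist, the achievable dimension
    is returned with a logged warning.  Accepts a :class:`DistanceMatrix` or
    a bare symmetric array (sample ids then default to ``s0..s{n-1}``).
    """
    if isinstance(d, DistanceMatrix):
        ids, values = d.sample_ids, d.values
    else:
        values = np.asarray(d, dtype=float)
        ids = [f"s{i}" for i in range(values.shape[0])]
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to embed")
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the maximum embeddable dimension {n - 1}")

    d2 = values**2
    row = d2.mean(axis=1, keepdims=True)
    grand = d2.mean()
    b = -0.5 * (d2 - row - row.T + grand)
    b = (b + b.T) / 2.0
    w, v = eigh(b)
    order = np.argsort(-w, kind="stable")
    w, v = w[order], v[:, order]

    tol = max(abs(w[0]), abs(w[-1]), 1.0e-300) * _EIG_REL_TOL
    n_pos = int((w > tol).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        logger.warning(
            "only %d positive eigenvalues available; returning a %d-dimensional "
            "embedding instead of %d",
            n_pos,
            k_eff,
            k,
        )
    neg_mass = float(np.abs(w[w < 0]).sum() / max(np.abs(w).sum(), 1e-300))
    if neg_mass > 1e-8:
        logger.info(
            "distance matrix is non-Euclidean: %.3g of the eigenvalue mass is "
            "negative",
            neg_mass,
        )
    coords = v[:, :k_eff] * np.sqrt(w[:k_eff])
    coords = _fix_signs(np.ascontiguousarray(coords))
    return MDSResult(list(ids), coords, w, k_eff, neg_mass)


def reconstructed_distances(r: MDSResult) -> DistanceMatrix:
    """Euclidean distances between the embedded coordinates."""
    if r.n_samples < 2:
        raise ValueError("nothing to reconstruct")
    values = squareform(pdist(r.coordinates)) if r.coordinates.size else np.zeros(
        (r.n_samples, r.n_samples)
    )
    return DistanceMatrix(
        list(r.sample_ids), values, "euclidean_reconstruction", "custom", 0, None
    )


def write_coordinates(r: MDSResult, path) -> None:
    df = pd.DataFrame(
        r.coordinates,
        index=r.sample_ids,
        columns=[f"dim{c + 1}" for c in range(r.coordinates.shape[1])],
    )
    df.to_csv(path, index_label="sample_id", float_format="%.10g")


def write_eigenvalues(r: MDSResult, path) -> None:
    pd.DataFrame({"eigenvalue": r.eigenvalues}).to_csv(
        path, index=False, float_format="%.10g"
    )


def plot_embedding(r: MDSResult, phenotypes=None, path=None, title: str = ""):
    """Scatter of dim1 vs dim2, colored by case/control when phenotypes given.

    Uses the Agg backend so headless runs need no display.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    xy = r.coordinates[:, :2] if r.coordinates.shape[1] >= 2 else np.column_stack(
        [r.coordinates[:, 0], np.zeros(r.n_samples)]
    )
    if phenotypes is not None:
        for label, color in (("case", "tab:blue"), ("control", "tab:red")):
            sel = [i for i, s in enumerate(r.sample_ids)
                   if s in phenotypes and phenotypes[s] == label]
            ax.scatter(xy[sel, 0], xy[sel, 1], s=12, c=color, label=label, alpha=0.7)
        ax.legend(frameon=False)
    else:
        ax.scatter(xy[:, 0], xy[:, 1], s=12, c="tab:gray", alpha=0.7)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
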