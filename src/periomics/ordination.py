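"""Bray-Curtis dissimilarity and unconstrained ordination (PCoA, nMDS).

PCoA is implemented on the Gower-centred matrix ``G = -1/2 J D^2 J`` so
that the same eigenbasis can be reused by the constrained CAP analysis;
negative eigenvalues (Bray-Curtis is non-Euclidean) are retained for
diagnostics but excluded from coordinates.  Non-metric MDS delegates to
SMACOF with isotonic regression on rank-transformed dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from periomics.tables import FeatureTable, TableError


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between sample rows.

    ``d(x, y) = sum |x_f - y_f| / sum (x_f + y_f)``.  All-zero samples must
    have been flagged at construction: the dissimilarity is undefined for a
    pair of empty profiles, so their presence is rejected with the ids.
    """
    if table.zero_samples:
        raise TableError(
            f"Bray-Curtis undefined for all-zero samples {list(table.zero_samples)}; "
            "drop or flag-exclude them first"
        )
    condensed = pdist(table.values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class Ordination:
    """Coordinates of an ordination plus method diagnostics."""

    coordinates: pd.DataFrame  # samples x axes
    method: str
    eigenvalues: np.ndarray | None = None   # PCoA, full spectrum descending
    negative_mass: float = 0.0              # |sum of negative eigenvalues| / sum |eigenvalues|
    stress: float | None = None             # nMDS Kruskal stress-1
    extras: dict = field(default_factory=dict)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centre a squared-distance-ready matrix: ``-1/2 J D^2 J``."""
    d = np.asarray(d, dtype=float)
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa_eig(dm: DistanceMatrix, tol: float = 1e-10):
    """Eigendecompose the Gower-centred matrix; eigenvalues descending.

    Returns ``(eigvals, eigvecs)`` with orthonormal eigenvectors as
    columns, the shared substrate of :func:`pcoa` and the CAP model.
    """
    g = gower_center(dm.data)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pcoa(dm: DistanceMatrix, tol: float = 1e-8) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for all
    eigenvalues above ``tol`` (relative to the largest); the negative
    eigenvalue mass is reported so non-Euclidean distortion is visible.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("pcoa needs at least 3 samples")
    vals, vecs = pcoa_eig(dm)
    cut = tol * max(vals.max(), 1.0)
    pos = vals > cut
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    neg = vals[vals < 0]
    neg_mass = float(np.abs(neg).sum() / np.abs(vals).sum()) if len(neg) else 0.0
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        method="pcoa", eigenvalues=vals, negative_mass=neg_mass,
    )


def nmds(dm: DistanceMatrix, k: int = 2, restarts: int = 20,
         seed: int | None = 0) -> Ordination:
    """Non-metric MDS by stress majorization (SMACOF) with isotonic regression.

    Runs ``restarts`` seeded random initialisations and keeps the lowest
    Kruskal stress-1 configuration.
    """
    n = dm.shape[0]
    if n <= k + 1:
        raise ValueError(f"nmds needs more than k+1={k + 1} samples, got {n}")
    model = MDS(n_components=k, metric_mds=False, n_init=restarts,
                metric="precomputed", init="random", random_state=seed,
                normalized_stress=True, max_iter=500, eps=1e-9)
    coords = model.fit_transform(dm.data)
    axes = [f"MDS{i + 1}" for i in range(k)]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        method="nmds", stress=float(model.stress_),
    )
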