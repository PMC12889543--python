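"""Embedding utilities: chromatin-graph geodesics and score-matrix MDS.

A coverage-weighted contact matrix is turned into a local discrepancy
matrix Y_ij = 1/(A_ij + 0.1) (strong contacts = short edges), geodesic
distances are taken as all-pairs shortest paths over the complete graph
with those edge weights, and 2-D coordinates come from non-metric MDS.
A matrix of pairwise reproducibility scores P in [0, 1] is embedded the
same way after the monotone transform D_ij = (1 - P_ij)^2, which
emphasizes large dissimilarities while preserving rank order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import floyd_warshall
from sklearn.manifold import MDS


@dataclass
class DistanceMatrices:
    """Local discrepancies Y and geodesic (shortest-path) distances Dgeo."""

    Y: np.ndarray
    Dgeo: np.ndarray


def contact_to_geodesic(A: np.ndarray) -> DistanceMatrices:
    """Geodesic distances over the chromatin graph of a contact matrix.

    Y_ij = 1/(A_ij + 0.1); the +0.1 offset keeps all edges finite, so the
    graph is complete.  Dgeo is the Floyd-Warshall all-pairs shortest-path
    matrix with zero diagonal.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("contact matrix must be nonnegative")
    Y = 1.0 / (A + 0.1)
    W = Y.copy()
    np.fill_diagonal(W, 0.0)
    Dgeo = floyd_warshall(W, directed=False)
    return DistanceMatrices(Y=Y, Dgeo=Dgeo)


def scores_to_dissimilarity(P: np.ndarray) -> np.ndarray:
    """Square-transform a pairwise score matrix: D_ij = (1 - P_ij)^2."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("scores must lie in [0, 1]")
    if not np.allclose(P, P.T):
        raise ValueError("score matrix must be symmetric")
    return (1.0 - P) ** 2


def embed_2d(D: np.ndarray, seed: int = 0,
             n_init: int = 4, max_iter: int = 500) -> tuple[np.ndarray, float]:
    """Non-metric MDS of a symmetric distance matrix into 2-D.

    Returns (coordinates, stress).  Because a non-metric solution is
    defined only up to scale, the coordinates are rescaled by the
    least-squares factor matching embedded distances to D, so exactly
    embeddable configurations reproduce the input distances.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("D must be a symmetric square matrix")
    n = D.shape[0]
    if n == 1:
        return np.zeros((1, 2)), 0.0
    if n == 2:
        d = D[0, 1]
        return np.array([[0.0, 0.0], [d, 0.0]]), 0.0
    mds = MDS(n_components=2, metric_mds=False, metric="precomputed",
              init="random", random_state=seed, n_init=n_init,
              max_iter=max_iter, normalized_stress="auto")
    coords = mds.fit_transform(D)
    emb = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    denom = (emb ** 2).sum()
    if denom > 0:
        coords = coords * ((D * emb).sum() / denom)
    return coords, float(mds.stress_)
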