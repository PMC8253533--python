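"""Classical (Torgerson) metric multidimensional scaling — principal
coordinates of a dissimilarity matrix.

Given pairwise dissimilarities D, Gower double-centering gives
``B = -1/2 * J (D ∘ D) J`` with ``J = I - 11'/n``; coordinates are the
eigenvectors of B scaled by the square roots of its positive eigenvalues.
Rst matrices are generally non-Euclidean, so negative eigenvalues can occur;
they are dropped (standard PCoA practice) and reported as a distortion
diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Embedding", "classical_mds"]


@dataclass
class Embedding:
    """Low-dimensional coordinates for the populations behind a distance matrix."""

    labels: list[str]
    coordinates: np.ndarray  # (n, k), axes ordered by decreasing eigenvalue
    eigenvalues: np.ndarray  # retained (positive) eigenvalues, descending
    proportion_explained: np.ndarray  # eigenvalue / sum of positive eigenvalues
    negative_eigenvalues: np.ndarray  # dropped negative spectrum (diagnostic)
    truncated: bool = False  # requested dims exceeded the positive eigencount

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {D.shape}")
    if not np.allclose(D, D.T, rtol=0, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, rtol=0, atol=1e-12):
        raise ValueError("distance matrix has a nonzero diagonal")
    if (D < -1e-12).any():
        raise ValueError("distance matrix has negative entries")
    return np.maximum(D, 0.0)


def classical_mds(
    D: np.ndarray, k: int = 2, labels: list[str] | None = None
) -> Embedding:
    """Embed a dissimilarity matrix into k dimensions by principal coordinates.

    Deterministic sign convention: within each axis the largest-magnitude
    loading is made positive.  If fewer than k eigenvalues are positive the
    embedding is truncated and flagged (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = _validate_distance_matrix(D)
    n = D.shape[0]
    labels = list(labels) if labels is not None else [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2.0  # symmetrize against round-off
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigval[0]), 1.0)
    positive = eigval > tol
    pos_vals = eigval[positive]
    neg_vals = eigval[eigval < -tol]

    truncated = k > pos_vals.size
    if truncated and (D > 0).any():
        warnings.warn(
            f"requested {k} axes but only {pos_vals.size} positive "
            "eigenvalues; extra axes are zero",
            stacklevel=2,
        )
    k_pos = min(k, pos_vals.size)

    # extra requested axes beyond the positive eigencount stay at zero
    coords = np.zeros((n, k))
    coords[:, :k_pos] = eigvec[:, :k_pos] * np.sqrt(pos_vals[:k_pos])
    # deterministic sign: largest-magnitude loading per axis made positive
    for axis in range(k_pos):
        col = coords[:, axis]
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            coords[:, axis] = -col

    total_pos = pos_vals.sum() if pos_vals.size else 1.0
    return Embedding(
        labels=labels,
        coordinates=coords,
        eigenvalues=pos_vals[:k_pos],
        proportion_explained=pos_vals[:k_pos] / total_pos,
        negative_eigenvalues=neg_vals,
        truncated=truncated,
    )
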