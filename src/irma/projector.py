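"""Orthogonal correction projectors.

The correction matrix ``Psi = I - sum_i v_i v_i^T`` projects feature vectors
onto the orthogonal complement of the accumulated discriminative directions
``v_i``.  Applying it to data (or to the relevance parameterization of a
classifier in training) removes the information residing in
``V = span{v_0, .., v_{J-1}}`` from consideration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Projector", "build_projector", "harmonize_features", "subspace_complement_check"]


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class Projector:
    """Orthonormal direction set and its complement projector matrix."""

    vectors: np.ndarray  # (J, N), rows orthonormal; J may be 0
    matrix: np.ndarray  # (N, N), I - sum v v^T

    @property
    def dim(self) -> int:
        """Number of removed directions J."""
        return self.vectors.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]


def _orthonormalize(vectors, n_features=None, tol: float = 1e-10) -> np.ndarray:
    """Sequential Gram-Schmidt; rejects (near-)dependent or zero vectors."""
    rows: list[np.ndarray] = []
    for i, v in enumerate(vectors):
        v = np.asarray(v, dtype=float).ravel()
        if n_features is None:
            n_features = v.size
        if v.size != n_features:
            raise ValueError("all vectors must share one dimension")
        for u in rows:
            v = v - (u @ v) * u
        norm = np.linalg.norm(v)
        if norm <= tol:
            raise DegenerateInputError(f"vector {i} is zero or linearly dependent within tolerance")
        rows.append(v / norm)
    if not rows:
        if n_features is None:
            raise ValueError("an empty vector list needs an explicit dimension")
        return np.empty((0, n_features))
    return np.stack(rows)


def build_projector(vectors, n_features: int | None = None) -> Projector:
    """Build ``Psi = I - sum v v^T`` from (re-orthonormalized) directions.

    An empty list yields the identity (no correction); dependent or zero
    input vectors raise :class:`DegenerateInputError`.
    """
    V = _orthonormalize(vectors, n_features)
    psi = np.eye(V.shape[1]) - V.T @ V
    return Projector(vectors=V, matrix=psi)


def harmonize_features(X: np.ndarray, projector: Projector) -> np.ndarray:
    """Apply the correction matrix directly to feature rows: ``X @ Psi``.

    Output rows are orthogonal to every accumulated direction; the map is
    idempotent, so harmonizing twice equals harmonizing once.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != projector.n_features:
        raise ValueError("feature dimension does not match the projector")
    return X @ projector.matrix


def subspace_complement_check(projector: Projector, X: np.ndarray) -> float:
    """Certificate of membership in the complement subspace U.

    Returns ``max_i,j |<x_i, v_j>|`` over samples and accumulated directions;
    ~0 certifies that ``X`` carries no component inside V.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if projector.dim == 0:
        return 0.0
    return float(np.max(np.abs(X @ projector.vectors.T)))
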