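"""PCA coordinate system from a space-defining reference cohort.

All data — whatever its center of origin — is expressed in one fixed
coordinate system: the principal axes of a preprocessed reference cohort,
keeping the smallest number of components whose cumulative explained
variance reaches the target (default 80%).  Features are subsequently
z-scored with the mean/sd of the reference healthy controls so the model
sees roughly comparable magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "PCABasis",
    "global_mean_normalize",
    "fit_reference_space",
    "fit_zscore",
    "extract_features",
    "zscore_features",
    "inverse_zscore",
]


class DegenerateInputError(ValueError):
    pass


@dataclass
class PCABasis:
    """Fixed affine coordinate system for feature extraction.

    ``components`` G is D x K with orthonormal columns (G^T G = I); feature
    extraction is ``x = (X - reference_mean) G`` and back-projection
    ``X ~= reference_mean + x G^T`` (lossy when K < D).  ``mask_index`` maps
    the D entries back to voxel positions when the vectors came from masked
    volumes (C-order flattening of the volume array).
    """

    components: np.ndarray  # (D, K)
    reference_mean: np.ndarray  # (D,)
    variance_fractions: np.ndarray  # (K,)
    zscore_mean: np.ndarray | None = None  # (K,)
    zscore_sd: np.ndarray | None = None  # (K,)
    mask_index: np.ndarray | None = None  # (D,) flat voxel indices

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_input(self) -> int:
        return self.components.shape[0]


def global_mean_normalize(vectors: np.ndarray) -> np.ndarray:
    """Divide each sample by its mean value so the mean becomes unity.

    ``vectors`` holds already-masked voxel values, one row per subject (a
    single 1-D vector is also accepted).  A nonpositive mean signals an
    invalid image.
    """
    V = np.asarray(vectors, dtype=float)
    single = V.ndim == 1
    V = np.atleast_2d(V)
    means = V.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("global mean normalization requires a positive masked mean")
    out = V / means[:, None]
    return out[0] if single else out


def fit_reference_space(reference: np.ndarray, variance_target: float = 0.8) -> PCABasis:
    """Principal axes of the mean-centered reference cohort.

    Keeps the smallest K whose cumulative explained-variance fraction
    reaches ``variance_target``; each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 2 or reference.shape[0] < 2:
        raise ValueError("reference must be a 2-D array with at least two samples")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    if np.allclose(reference, reference[0], atol=0):
        raise DegenerateInputError("reference cohort has zero variance")

    pca = PCA(n_components=min(reference.shape[0] - 1, reference.shape[1]), svd_solver="full")
    pca.fit(reference)
    fractions = pca.explained_variance_ratio_
    cum = np.cumsum(fractions)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(fractions))
    G = pca.components_[:k].T.copy()
    for j in range(k):
        i = np.argmax(np.abs(G[:, j]))
        if G[i, j] < 0:
            G[:, j] = -G[:, j]
    return PCABasis(
        components=G,
        reference_mean=pca.mean_.copy(),
        variance_fractions=fractions[:k].copy(),
    )


def extract_features(X: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Project preprocessed vectors into the basis: ``(X - mean) G``."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != basis.n_input:
        raise ValueError("input dimension does not match the basis")
    return (X - basis.reference_mean) @ basis.components


def fit_zscore(basis: PCABasis, reference_hc_features: np.ndarray) -> PCABasis:
    """Store per-feature z-scoring parameters from reference healthy controls."""
    F = np.atleast_2d(np.asarray(reference_hc_features, dtype=float))
    if F.shape[1] != basis.n_components:
        raise ValueError("feature dimension does not match the basis")
    sd = F.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateInputError("a reference feature has zero standard deviation")
    basis.zscore_mean = F.mean(axis=0)
    basis.zscore_sd = sd
    return basis


def _require_zscore(basis: PCABasis) -> None:
    if basis.zscore_mean is None or basis.zscore_sd is None:
        raise ValueError("z-scoring parameters have not been fitted (call fit_zscore)")


def zscore_features(x: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Column-wise ``(x - mean) / sd`` with reference-control parameters."""
    _require_zscore(basis)
    return (np.asarray(x, dtype=float) - basis.zscore_mean) / basis.zscore_sd


def inverse_zscore(x: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Undo :func:`zscore_features`; composes to the identity."""
    _require_zscore(basis)
    return np.asarray(x, dtype=float) * basis.zscore_sd + basis.zscore_mean
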