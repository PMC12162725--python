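"""Analytic reconstruction of corrected and removed profiles in voxel space.

A feature vector ``x`` (scaling already undone) back-projects as
``X ~= reference_mean + x G^T``.  Under a correction projector ``Psi`` the
reconstruction splits exactly into a corrected image and a removed profile:

    X_corr = reference_mean + (x Psi) G^T
    X_rem  = (x (I - Psi)) G^T
    X_corr + X_rem = reconstruct(x)

so the removed profile is pure span-V content while the reference mean
stays with the corrected image, keeping the removed map interpretable as
the center-specific signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .feature_space import PCABasis
from .projector import Projector

__all__ = ["VoxelProfile", "reconstruct", "removed_profile", "corrected_image", "voxel_zscore", "voxel_profile"]

logger = logging.getLogger(__name__)


@dataclass
class VoxelProfile:
    """Original, removed and corrected voxel-space profiles of one vector."""

    original: np.ndarray
    removed: np.ndarray
    corrected: np.ndarray


def reconstruct(x: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Back-project features into voxel space: ``reference_mean + x G^T``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != basis.n_components:
        raise ValueError("feature dimension does not match the basis")
    return basis.reference_mean + x @ basis.components.T


def removed_profile(x: np.ndarray, projector: Projector, basis: PCABasis) -> np.ndarray:
    """Voxel-space content of ``x`` that resides in V: ``(x (I-Psi)) G^T``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != basis.n_components:
        raise ValueError("feature dimension does not match the basis")
    removed_coords = x - x @ projector.matrix
    return removed_coords @ basis.components.T


def corrected_image(x: np.ndarray, projector: Projector, basis: PCABasis) -> np.ndarray:
    """Center-corrected reconstruction ``reference_mean + (x Psi) G^T``."""
    x = np.asarray(x, dtype=float)
    return reconstruct(x @ projector.matrix, basis)


def voxel_profile(x: np.ndarray, projector: Projector, basis: PCABasis) -> VoxelProfile:
    """All three profiles at once; original = corrected + removed exactly."""
    return VoxelProfile(
        original=reconstruct(x, basis),
        removed=removed_profile(x, projector, basis),
        corrected=corrected_image(x, projector, basis),
    )


def voxel_zscore(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Voxel-wise z-score against reference volumes (rows = subjects).

    Voxels with zero reference variance are set to 0 and a warning logged.
    """
    X = np.asarray(X, dtype=float)
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    mean = reference.mean(axis=0)
    sd = reference.std(axis=0, ddof=1)
    zero = sd <= 0
    if np.any(zero):
        logger.warning("%d zero-variance voxels set to 0 in z-map", int(zero.sum()))
    sd_safe = np.where(zero, 1.0, sd)
    z = (X - mean) / sd_safe
    if X.ndim == 1:
        z[zero] = 0.0
    else:
        z[:, zero] = 0.0
    return z
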