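"""Optional NIfTI I/O for users starting from (already spatially
normalized and smoothed) volumes plus a binary grey-matter mask.

The mask defines an ordered flat index list (C-order of the volume array);
the same ordering is stored with the PCA basis so voxel-space maps are
unambiguous on the way back.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

__all__ = ["load_mask", "load_masked_volumes", "save_map"]


def load_mask(path) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Return (flat voxel indices, volume shape, affine) of a binary mask."""
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    idx = np.flatnonzero(mask.ravel(order="C"))
    if idx.size == 0:
        raise ValueError("mask selects no voxels")
    return idx, mask.shape, img.affine


def load_masked_volumes(paths, mask_index: np.ndarray, shape: tuple) -> np.ndarray:
    """Stack masked, flattened volumes into a subjects x voxels matrix."""
    rows = []
    for p in paths:
        vol = np.asarray(nib.load(str(p)).dataobj, dtype=float)
        if vol.shape != tuple(shape):
            raise ValueError(f"volume {p} has shape {vol.shape}, expected {tuple(shape)}")
        rows.append(vol.ravel(order="C")[mask_index])
    return np.stack(rows)


def save_map(values: np.ndarray, mask_index: np.ndarray, shape: tuple, affine: np.ndarray, path) -> None:
    """Write a masked voxel vector back into a full volume NIfTI file."""
    vol = np.zeros(int(np.prod(shape)), dtype=float)
    vol[mask_index] = np.asarray(values, dtype=float)
    nib.save(nib.Nifti1Image(vol.reshape(shape), affine), str(path))
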