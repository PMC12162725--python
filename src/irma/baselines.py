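"""Center-wise z-scoring, the statistics-based comparator.

Each feature is z-scored separately per center, with mean and standard
deviation estimated from that center's healthy controls only and then
applied to all of that center's samples.  This aligns per-center control
distributions feature by feature but — unlike subspace correction — uses a
different affine map per center, so it preserves within-center rank order
while possibly reordering comparable samples across centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CenterScaler", "fit_center_scaler", "apply_center_scaler"]


@dataclass
class CenterScaler:
    """Per-center, per-feature location/scale estimated from controls."""

    means: dict  # center -> (K,) array
    sds: dict  # center -> (K,) array, strictly positive

    @property
    def centers(self) -> list:
        return list(self.means)


def fit_center_scaler(features: np.ndarray, centers: np.ndarray, hc_mask: np.ndarray) -> CenterScaler:
    """Estimate per-center parameters from that center's healthy controls.

    ``hc_mask`` flags control rows; every center must contribute at least
    two controls.  Standard deviations use the unbiased (n-1) denominator.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    centers = np.asarray(centers)
    hc_mask = np.asarray(hc_mask, dtype=bool)
    means: dict = {}
    sds: dict = {}
    for c in np.unique(centers):
        block = X[(centers == c) & hc_mask]
        if block.shape[0] < 2:
            raise ValueError(f"center {c!r} has fewer than two healthy controls")
        sd = block.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError(f"center {c!r} has a zero-variance feature among its controls")
        means[c] = block.mean(axis=0)
        sds[c] = sd
    return CenterScaler(means=means, sds=sds)


def apply_center_scaler(features: np.ndarray, centers: np.ndarray, scaler: CenterScaler) -> np.ndarray:
    """Apply ``(x - mean_center) / sd_center`` row-wise."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    centers = np.asarray(centers)
    unknown = set(np.unique(centers)) - set(scaler.means)
    if unknown:
        raise KeyError(f"centers without fitted parameters: {sorted(map(str, unknown))}")
    out = np.empty_like(X)
    for c in np.unique(centers):
        mask = centers == c
        out[mask] = (X[mask] - scaler.means[c]) / scaler.sds[c]
    return out
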