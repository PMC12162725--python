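"""Subspace angles, per-feature group tests and score summaries.

Principal angles quantify how much of the information a trained disease
model uses overlaps with the center-specific subspace V: 0 degrees means a
shared direction, 90 degrees means the model used no center-specific
information at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from sklearn.metrics import roc_auc_score

__all__ = ["SubspaceAngleReport", "principal_angles", "count_significant_features", "multiclass_auc"]


class DegenerateInputError(ValueError):
    pass


@dataclass
class SubspaceAngleReport:
    """Principal angles in degrees, ascending; length = min(dim A, dim B)."""

    angles_deg: np.ndarray
    dim_a: int
    dim_b: int

    @property
    def max_angle(self) -> float:
        return float(self.angles_deg[-1])

    @property
    def min_angle(self) -> float:
        return float(self.angles_deg[0])


def _check_basis(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    norms = np.linalg.norm(M, axis=0)
    if np.any(norms <= 1e-12):
        raise DegenerateInputError(f"{name} contains a zero column")
    gram = M.T @ M
    if np.max(np.abs(gram - np.eye(M.shape[1]))) > 1e-6:
        raise ValueError(f"columns of {name} are not orthonormal within 1e-6")
    # re-orthonormalize to suppress drift below the tolerance
    q, _ = np.linalg.qr(M)
    return q


def principal_angles(A: np.ndarray, B: np.ndarray) -> SubspaceAngleReport:
    """Principal angles between the column spans of ``A`` and ``B``.

    Computed from the singular values of ``A^T B`` (clipped to [0, 1]);
    symmetric in its arguments and invariant to any rotation of either
    basis within its own span.
    """
    A = _check_basis(A, "A")
    B = _check_basis(B, "B")
    if A.shape[0] != B.shape[0]:
        raise ValueError("subspaces must live in the same ambient dimension")
    rad = linalg.subspace_angles(A, B)  # descending
    deg = np.sort(np.degrees(rad))
    return SubspaceAngleReport(angles_deg=deg, dim_a=A.shape[1], dim_b=B.shape[1])


def count_significant_features(
    features: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> tuple[int, np.ndarray]:
    """Per-feature Kruskal-Wallis tests across groups.

    Returns the number of features with p below the (optionally
    Bonferroni-divided) threshold together with all per-feature p-values.
    A feature constant across all samples gets p = 1 by convention.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or np.any(counts < 2):
        raise ValueError("need at least two groups with at least two samples each")
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        samples = [X[groups == g, j] for g in labels]
        if np.ptp(X[:, j]) == 0:
            pvals[j] = 1.0
            continue
        pvals[j] = stats.kruskal(*samples).pvalue
    threshold = alpha / X.shape[1] if bonferroni else alpha
    return int(np.sum(pvals < threshold)), pvals


def multiclass_auc(scores: np.ndarray, y_true: np.ndarray, classes=None) -> float:
    """Macro-averaged one-vs-rest rank AUC from per-class scores.

    ``scores`` column ``j`` scores membership of class ``classes[j]``
    (e.g. negated prototype distances); higher means more likely.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y_true = np.asarray(y_true)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC is undefined for a single class")
    if scores.shape[1] != len(classes):
        raise ValueError("score columns must match the class list")
    aucs = [
        roc_auc_score((y_true == c).astype(int), scores[:, j])
        for j, c in enumerate(classes)
        if 0 < np.sum(y_true == c) < len(y_true)
    ]
    return float(np.mean(aucs))
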