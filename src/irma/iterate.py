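"""The iterated relevance matrix analysis loop.

Repeatedly train a GMLVQ model to classify the acquisition center of
healthy-control samples, harvest the leading eigenvector of its relevance
matrix, project that direction out, and retrain — until repeated
cross-validation says the centers are no longer distinguishable (mean
balanced accuracy at or below chance, 1/C).  The accumulated directions
span the center-specific subspace V; the complement U is where
harmonized data and subsequently trained disease models live.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold

from .gmlvq import (
    GMLVQModel,
    TrainConfig,
    balanced_accuracy,
    leading_eigenvectors,
    predict,
    train_gmlvq,
)
from .projector import Projector, build_projector

__all__ = ["CVResult", "IRMAResult", "repeated_cv", "run_irma"]

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Repeated stratified cross-validation summary."""

    mean_bac: float
    ci_low: float
    ci_high: float
    fold_bacs: np.ndarray  # (repeats * folds,)
    per_class_recall: dict  # class -> mean recall over folds


@dataclass
class IRMAResult:
    """Outcome of the iterative subspace extraction.

    ``vectors`` (J, N) are the accumulated orthonormal center-discriminative
    directions defining V; ``cv_results[i]`` is the cross-validated
    performance under correction by the first ``i`` vectors (so the last
    entry is the at-or-below-chance evaluation that stopped the loop, when
    converged); ``models[i]`` is the full-data model trained at iteration
    ``i``.
    """

    vectors: np.ndarray
    cv_results: list[CVResult]
    models: list[GMLVQModel] = field(default_factory=list)
    converged: bool = True
    chance_level: float = 0.0

    @property
    def n_iterations(self) -> int:
        """Stopping iteration = number of accumulated vectors."""
        return self.vectors.shape[0]

    @property
    def bac_curve(self) -> np.ndarray:
        return np.array([r.mean_bac for r in self.cv_results])

    def projector(self, n_vectors: int | None = None) -> Projector:
        """Correction projector from the first ``n_vectors`` directions."""
        k = self.n_iterations if n_vectors is None else n_vectors
        return build_projector(self.vectors[:k], n_features=self.vectors.shape[1])


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    projector: Projector | None = None,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of a (restricted) model.

    Every repeat partitions the samples into ``folds`` stratified folds, a
    model is trained on each training split under the projector restriction,
    and balanced accuracy is measured on the held-out fold.  The 95%
    confidence interval uses the normal approximation over the
    repeats x folds fold scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < folds):
        small = classes[counts < folds]
        raise ValueError(f"classes {small.tolist()} have fewer samples than folds={folds}")
    config = config or TrainConfig()

    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    fold_bacs = []
    recall_sums = {c: 0.0 for c in classes}
    recall_counts = {c: 0 for c in classes}
    for train_idx, test_idx in splitter.split(X, y):
        model = train_gmlvq(X[train_idx], y[train_idx], config, projector)
        y_pred = predict(model, X[test_idx])
        y_test = y[test_idx]
        fold_bacs.append(balanced_accuracy(y_test, y_pred))
        for c in np.unique(y_test):
            mask = y_test == c
            recall_sums[c] += float(np.mean(y_pred[mask] == c))
            recall_counts[c] += 1
    fold_bacs = np.asarray(fold_bacs)
    mean = float(fold_bacs.mean())
    half = 1.959963984540054 * float(fold_bacs.std(ddof=1)) / np.sqrt(len(fold_bacs))
    recalls = {c: recall_sums[c] / max(recall_counts[c], 1) for c in classes}
    return CVResult(mean, mean - half, mean + half, fold_bacs, recalls)


def run_irma(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    repeats: int = 10,
    folds: int = 10,
    max_iter: int | None = None,
    seed: int = 0,
) -> IRMAResult:
    """Iteratively extract the class-discriminative subspace V.

    At iteration ``i`` the current correction (built from the ``i`` vectors
    accumulated so far) is evaluated by repeated cross-validation; if the
    mean balanced accuracy is at or below chance (1/C) the loop stops —
    a dataset with no class signal therefore yields an empty V.  Otherwise a
    model is trained on all samples under the current correction, the
    leading eigenvector of its relevance matrix is re-orthogonalized against
    V and appended, and the correction is rebuilt.  Reaching ``max_iter``
    (default: the feature count) without chance-level performance flags the
    result as non-converged rather than raising.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    classes = np.unique(y)
    chance = 1.0 / len(classes)
    if max_iter is None:
        max_iter = n_features
    if max_iter > n_features:
        raise ValueError("max_iter cannot exceed the feature count")
    config = config or TrainConfig()
    rng = np.random.SeedSequence(seed)
    cv_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(max_iter + 1)]

    vectors = np.empty((0, n_features))
    cv_results: list[CVResult] = []
    models: list[GMLVQModel] = []
    converged = False
    for i in range(max_iter + 1):
        proj = build_projector(vectors, n_features=n_features)
        res = repeated_cv(X, y, config, proj, repeats=repeats, folds=folds, seed=cv_seeds[i])
        cv_results.append(res)
        logger.info(
            "iteration %d: correction dim %d, CV BAC %.3f [%.3f, %.3f] (chance %.3f)",
            i, proj.dim, res.mean_bac, res.ci_low, res.ci_high, chance,
        )
        if res.mean_bac <= chance:
            logger.info("stopping: mean CV BAC %.3f <= chance %.3f", res.mean_bac, chance)
            converged = True
            break
        if i == max_iter:
            logger.warning("max_iter=%d reached without chance-level performance", max_iter)
            break
        model = train_gmlvq(X, y, config, proj)
        models.append(model)
        _, vecs = leading_eigenvectors(model.lambda_, 1)
        v = vecs[:, 0]
        # guard against numerical drift out of the complement of V
        v = v - vectors.T @ (vectors @ v)
        norm = np.linalg.norm(v)
        if norm <= 1e-10:
            logger.warning("leading eigenvector collapsed into V; stopping early")
            break
        vectors = np.vstack([vectors, v / norm])
        logger.info("iteration %d: appended direction, dim(V) now %d", i, vectors.shape[0])

    return IRMAResult(
        vectors=vectors,
        cv_results=cv_results,
        models=models,
        converged=converged,
        chance_level=chance,
    )
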