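"""Generalized matrix learning vector quantization (GMLVQ).

A nearest-prototype classifier whose distance is the quadratic form
``d(w, x) = (x - w)^T Lambda (x - w)`` with an adaptive relevance matrix
``Lambda = Omega^T Omega`` kept trace-normalized (``Tr(Lambda) = 1``).
Training minimizes the GLVQ cost

    E = sum_mu  (d+ - d-) / (d+ + d-)

by batch waypoint gradient descent, where ``d+`` is the distance of sample
``mu`` to the prototype of its own class and ``d-`` the distance to the
closest prototype of any other class.  Optionally every update of ``Omega``
is right-multiplied by an orthogonal projector, restricting the learned
relevances to a subspace.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrainConfig",
    "GMLVQModel",
    "normalize_omega",
    "relevance_distance",
    "glvq_cost",
    "train_gmlvq",
    "predict",
    "balanced_accuracy",
    "leading_eigenvectors",
    "discriminative_projection",
]


class InvalidModelError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the standard recipe for this model family: 30 epochs of
    waypoint gradient descent with identity activation and initial step
    sizes 1 (prototypes) and 2 (relevance matrix).
    """

    epochs: int = 30
    step_prototypes: float = 1.0
    step_matrix: float = 2.0
    waypoint_window: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.step_prototypes <= 0 or self.step_matrix <= 0:
            raise ValueError("step sizes must be positive")


@dataclass
class GMLVQModel:
    """Trained prototypes and relevance parameterization.

    ``prototypes`` has one row per class, ordered as ``classes``;
    ``lambda_`` is always ``omega.T @ omega`` with unit trace.
    """

    prototypes: np.ndarray  # (C, N)
    omega: np.ndarray  # (N, N)
    classes: np.ndarray  # (C,)
    training_trace: list = field(default_factory=list)

    @property
    def lambda_(self) -> np.ndarray:
        return self.omega.T @ self.omega

    @property
    def n_features(self) -> int:
        return self.prototypes.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        lam = self.lambda_
        if not np.allclose(lam, lam.T, atol=atol):
            raise InvalidModelError("relevance matrix is not symmetric")
        if abs(np.trace(lam) - 1.0) > atol:
            raise InvalidModelError("relevance matrix trace differs from 1")
        if self.prototypes.shape[0] != len(self.classes):
            raise InvalidModelError("exactly one prototype per class is required")


def normalize_omega(omega: np.ndarray) -> np.ndarray:
    """Scale ``omega`` so that ``Tr(Omega^T Omega) = sum Omega_ij^2 = 1``."""
    omega = np.asarray(omega, dtype=float)
    ssq = float(np.sum(omega**2))
    if ssq <= 0.0:
        raise InvalidModelError("cannot normalize an all-zero omega matrix")
    return omega / np.sqrt(ssq)


def relevance_distance(x: np.ndarray, w: np.ndarray, lam: np.ndarray) -> float:
    """Generalized squared Euclidean distance ``(x-w)^T Lambda (x-w)``."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if x.shape != w.shape or lam.shape != (x.size, x.size):
        raise ValueError("dimension mismatch between x, w and lambda")
    d = x - w
    return float(d @ lam @ d)


def _pairwise_sq_distances(X: np.ndarray, W: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """(P, C) matrix of ||Omega (x - w)||^2."""
    diff = X[:, None, :] - W[None, :, :]
    proj = diff @ omega.T
    return np.einsum("pcn,pcn->pc", proj, proj)


def _margins(X, y_idx, W, omega):
    """Per-sample d+, d-, index of the closest wrong-class prototype."""
    d = _pairwise_sq_distances(X, W, omega)
    rows = np.arange(len(X))
    d_plus = d[rows, y_idx]
    d_other = d.copy()
    d_other[rows, y_idx] = np.inf
    j_minus = np.argmin(d_other, axis=1)
    d_minus = d_other[rows, j_minus]
    return d_plus, d_minus, j_minus


def _cost_arrays(X, y_idx, W, omega) -> float:
    d_plus, d_minus, _ = _margins(X, y_idx, W, omega)
    s = d_plus + d_minus
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(s > 0, (d_plus - d_minus) / s, 0.0)
    return float(np.sum(mu))


def _encode(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lookup[v] for v in y])
    except KeyError as exc:  # pragma: no cover - defensive
        raise InvalidModelError(f"label {exc.args[0]!r} has no prototype") from exc


def glvq_cost(model: GMLVQModel, X: np.ndarray, y: np.ndarray) -> float:
    """GLVQ cost of ``model`` on labeled data; each term lies in [-1, 1].

    A term with ``d+ = d- = 0`` (sample coincides with two prototypes) is
    defined as 0, removing the singularity.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    missing = set(np.unique(y)) - set(model.classes.tolist())
    if missing:
        raise InvalidModelError(f"classes without a prototype: {sorted(map(str, missing))}")
    y_idx = _encode(np.asarray(y), model.classes)
    return _cost_arrays(X, y_idx, model.prototypes, model.omega)


def _gradients(X, y_idx, W, omega):
    """Batch gradients of the summed cost, divided by the sample count."""
    P = len(X)
    d_plus, d_minus, j_minus = _margins(X, y_idx, W, omega)
    s = d_plus + d_minus
    ok = s > 0
    s_safe = np.where(ok, s, 1.0)
    gamma_p = np.where(ok, 2.0 * d_minus / s_safe**2, 0.0)
    gamma_m = np.where(ok, -2.0 * d_plus / s_safe**2, 0.0)

    rows = np.arange(P)
    diff = X[:, None, :] - W[None, :, :]
    delta_p = diff[rows, y_idx]
    delta_m = diff[rows, j_minus]

    lam = omega.T @ omega
    gW = np.zeros_like(W)
    np.add.at(gW, y_idx, -2.0 * gamma_p[:, None] * (delta_p @ lam))
    np.add.at(gW, j_minus, -2.0 * gamma_m[:, None] * (delta_m @ lam))

    S = delta_p.T @ (gamma_p[:, None] * delta_p) + delta_m.T @ (gamma_m[:, None] * delta_m)
    gOmega = 2.0 * omega @ S
    return gW / P, gOmega / P


def train_gmlvq(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None, projector=None) -> GMLVQModel:
    """Train a GMLVQ model by batch waypoint gradient descent.

    Prototypes start at the class-conditional means and ``Omega`` at the
    (projected, trace-normalized) identity, so training is deterministic
    given the data.  Each epoch takes one raw steepest-descent step; the
    average of the last ``waypoint_window`` states replaces the raw step
    whenever it attains a lower cost, and a step that would increase the
    cost is rejected while both step sizes are halved (floor 1e-6).  When a
    projector is supplied, every candidate ``Omega`` is right-multiplied by
    its matrix before trace normalization, which confines the learned
    relevances to the projector's range.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if np.any(counts < 1):  # pragma: no cover - unique() guarantees >= 1
        raise ValueError("every class needs at least one sample")
    y_idx = _encode(y, classes)

    psi = None
    if projector is not None:
        psi = np.asarray(projector.matrix if hasattr(projector, "matrix") else projector, dtype=float)
        if psi.shape != (X.shape[1], X.shape[1]):
            raise ValueError("projector dimension does not match the data")

    def constrain(omega: np.ndarray) -> np.ndarray:
        if psi is not None:
            omega = omega @ psi
        return normalize_omega(omega)

    W = np.stack([X[y_idx == i].mean(axis=0) for i in range(len(classes))])
    omega = constrain(np.eye(X.shape[1]))

    lr_w = config.step_prototypes
    lr_o = config.step_matrix
    window: deque = deque(maxlen=config.waypoint_window)
    cost_cur = _cost_arrays(X, y_idx, W, omega)
    trace = [cost_cur]

    for _ in range(config.epochs):
        gW, gO = _gradients(X, y_idx, W, omega)
        W_raw = W - lr_w * gW
        O_raw = constrain(omega - lr_o * gO)
        window.append((W_raw, O_raw))
        W_avg = np.mean([s[0] for s in window], axis=0)
        O_avg = constrain(np.mean([s[1] for s in window], axis=0))

        c_raw = _cost_arrays(X, y_idx, W_raw, O_raw)
        c_avg = _cost_arrays(X, y_idx, W_avg, O_avg)
        if c_avg < c_raw:
            cand, c_cand = (W_avg, O_avg), c_avg
        else:
            cand, c_cand = (W_raw, O_raw), c_raw
        if c_cand <= cost_cur:
            W, omega = cand
            cost_cur = c_cand
        else:
            lr_w = max(lr_w / 2.0, 1e-6)
            lr_o = max(lr_o / 2.0, 1e-6)
        trace.append(cost_cur)

    model = GMLVQModel(prototypes=W, omega=omega, classes=classes, training_trace=trace)
    model.validate()
    return model


def predict(model: GMLVQModel, X: np.ndarray) -> np.ndarray:
    """Label of the nearest prototype under the relevance distance.

    Exact ties are broken toward the smallest class index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError("feature dimension does not match the model")
    d = _pairwise_sq_distances(X, model.prototypes, model.omega)
    return model.classes[np.argmin(d, axis=1)]


def decision_scores(model: GMLVQModel, X: np.ndarray) -> np.ndarray:
    """Per-class scores (negated relevance distances), higher is closer."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return -_pairwise_sq_distances(X, model.prototypes, model.omega)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall; chance level is 1/C for C classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    classes = np.unique(y_true)
    recalls = []
    for c in classes:
        mask = y_true == c
        if not np.any(mask):  # pragma: no cover - unique() guarantees presence
            raise ValueError(f"class {c!r} has no true samples")
        recalls.append(float(np.mean(y_pred[mask] == c)))
    return float(np.mean(recalls))


def leading_eigenvectors(lam: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-``m`` eigenpairs of a symmetric PSD matrix, eigenvalues descending.

    Returns ``(values, vectors)`` with unit-norm eigenvector columns whose
    largest-magnitude entry is made positive (sign convention).
    """
    lam = np.asarray(lam, dtype=float)
    if not np.allclose(lam, lam.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    if m > lam.shape[0]:
        raise ValueError("cannot request more eigenvectors than dimensions")
    vals, vecs = np.linalg.eigh(lam)
    order = np.argsort(vals)[::-1][:m]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


def discriminative_projection(model: GMLVQModel, X: np.ndarray) -> np.ndarray:
    """Coordinates of rows of ``X`` on the two leading relevance eigenvectors.

    The same mapping applies to the prototypes, giving the model's
    two-dimensional decision-space visualization.
    """
    _, vecs = leading_eigenvectors(model.lambda_, 2)
    return np.atleast_2d(np.asarray(X, dtype=float)) @ vecs
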