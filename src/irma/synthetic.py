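"""Seeded multi-center, multi-disease synthetic feature data.

Emulates the harmonization setting: healthy-control cohorts from C centers
share one common distribution except for a fixed per-center mean offset
confined to a planted low-dimensional subspace V* (the center effect), and
each disease adds a mean shift along a direction at a controllable angle to
V*.  The planted truth gives ground truth for subspace recovery, stopping
behavior and signal preservation.

Defaults mirror the reference study conditions used throughout the test
suite: four centers, 31 features, a three-dimensional center subspace with
2-SD offsets, 30 controls per center, three diseases (one cohort of 35 per
center, as in a multi-center study where each center contributes one
diagnosis) shifted by 3 SD along directions orthogonal to V*, and unit
isotropic Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledFeatureSet
from .diagnostics import principal_angles

__all__ = ["SyntheticTruth", "make_truth", "generate_multicenter", "recovery_error"]


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic multi-center data set."""

    v_star: np.ndarray  # (k, N) orthonormal rows: the center subspace
    center_offsets: np.ndarray  # (C, k) in units of within-class SD
    disease_directions: np.ndarray  # (n_dis, N) orthonormal rows
    disease_effects: np.ndarray  # (n_dis,) in units of within-class SD
    disease_angle_deg: float
    noise_sd: float
    n_controls: np.ndarray  # (C,)
    n_patients: np.ndarray  # (C, n_dis)
    seed: int
    noise: str = "gaussian"  # "gaussian" or "t5" (heavy-tailed)
    global_mean: np.ndarray | None = None

    @property
    def n_centers(self) -> int:
        return self.center_offsets.shape[0]

    @property
    def n_features(self) -> int:
        return self.v_star.shape[1]

    @property
    def center_dim(self) -> int:
        return self.v_star.shape[0]


def _random_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """(k, n) matrix with orthonormal rows from a Haar-ish QR draw."""
    if k == 0:
        return np.empty((0, n))
    q, r = np.linalg.qr(rng.standard_normal((n, k)))
    return (q * np.sign(np.where(np.diag(r) == 0, 1.0, np.diag(r)))).T


def make_truth(
    n_centers: int = 4,
    n_features: int = 31,
    center_dim: int = 3,
    offset_scale: float = 2.0,
    n_diseases: int = 3,
    disease_effect: float = 3.0,
    disease_angle_deg: float = 90.0,
    n_controls_per_center: int = 30,
    n_patients_per_cohort: int = 35,
    noise_sd: float = 1.0,
    noise: str = "gaussian",
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a planted truth.

    Each center's offset is a random direction inside V* scaled to
    ``offset_scale`` within-class SDs.  Disease direction ``d`` is
    ``cos(a) u_d + sin(a) w_d`` with ``u_d`` orthonormal inside V* and
    ``w_d`` orthonormal in its complement, so every principal angle between
    the disease span and V* equals ``disease_angle_deg`` by construction.
    Disease cohort ``d`` is hosted at center ``d`` (one diagnosis per
    center), as in a retrospectively pooled multi-center study.
    """
    if center_dim + n_diseases > n_features:
        raise ValueError("center_dim + n_diseases must not exceed n_features")
    theta = np.radians(disease_angle_deg)
    if n_diseases > 0 and abs(np.cos(theta)) > 1e-12 and n_diseases > center_dim:
        raise ValueError("more diseases than center dimensions at a non-orthogonal angle")

    rng = np.random.default_rng(seed)
    basis = _random_orthonormal(rng, n_features, center_dim + n_diseases)
    v_star = basis[:center_dim]
    complement = basis[center_dim:]

    if center_dim > 0 and offset_scale > 0:
        raw = rng.standard_normal((n_centers, center_dim))
        offsets = raw / np.linalg.norm(raw, axis=1, keepdims=True) * offset_scale
    else:
        offsets = np.zeros((n_centers, center_dim))

    if n_diseases > 0:
        if abs(np.cos(theta)) > 1e-12:
            dirs = np.cos(theta) * v_star[:n_diseases] + np.sin(theta) * complement
        else:
            dirs = complement
    else:
        dirs = np.empty((0, n_features))

    n_patients = np.zeros((n_centers, n_diseases), dtype=int)
    for d in range(n_diseases):
        n_patients[d % n_centers, d] = n_patients_per_cohort

    return SyntheticTruth(
        v_star=v_star,
        center_offsets=offsets,
        disease_directions=dirs,
        disease_effects=np.full(n_diseases, float(disease_effect)),
        disease_angle_deg=disease_angle_deg,
        noise_sd=noise_sd,
        n_controls=np.full(n_centers, n_controls_per_center, dtype=int),
        n_patients=n_patients,
        seed=seed,
        noise=noise,
    )


def generate_multicenter(truth: SyntheticTruth) -> LabeledFeatureSet:
    """Sample a labeled feature set from a planted truth.

    sample = global mean + center offset (inside V*) + disease shift
    (controls get none) + isotropic noise; deterministic per seed, and the
    noise stream does not depend on the offset values — regenerating with
    zeroed offsets yields the exact same noise realization (paired
    center-free oracle data).
    """
    if truth.center_dim > truth.n_features or truth.disease_directions.shape[0] > truth.n_features:
        raise ValueError("planted dimensions exceed the feature count")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x5EED]))
    mean = truth.global_mean if truth.global_mean is not None else np.zeros(truth.n_features)

    rows, center_labels, disease_labels = [], [], []
    for c in range(truth.n_centers):
        base = mean + truth.center_offsets[c] @ truth.v_star
        groups = [("", int(truth.n_controls[c]), np.zeros(truth.n_features))]
        for d in range(truth.n_patients.shape[1]):
            shift = truth.disease_effects[d] * truth.disease_directions[d]
            groups.append((f"D{d + 1}", int(truth.n_patients[c, d]), shift))
        for label, n, shift in groups:
            if n < 1:
                continue
            rows.append(np.tile(base + shift, (n, 1)))
            center_labels += [f"C{c + 1}"] * n
            disease_labels += [label] * n

    X = np.vstack(rows)
    if truth.noise == "gaussian":
        noise = rng.standard_normal(X.shape)
    elif truth.noise == "t5":
        noise = rng.standard_t(5, size=X.shape) / np.sqrt(5.0 / 3.0)
    else:
        raise ValueError(f"unknown noise kind {truth.noise!r}")
    X = X + truth.noise_sd * noise
    return LabeledFeatureSet(
        features=X,
        center=np.array(center_labels),
        disease=np.array(disease_labels),
    )


def recovery_error(v_hat: np.ndarray, truth: SyntheticTruth) -> float:
    """Largest principal angle (degrees) between span(v_hat) and span(V*)."""
    v_hat = np.atleast_2d(np.asarray(v_hat, dtype=float))
    if v_hat.shape[0] == 0:
        raise ValueError("recovered subspace is empty")
    report = principal_angles(v_hat.T, truth.v_star.T)
    return report.max_angle
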