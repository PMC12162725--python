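"""JSON serialization of models, subspaces and PCA bases.

Plain JSON with full-precision floats (Python's shortest round-trip repr),
so deterministic fields survive a write/read cycle bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .feature_space import PCABasis
from .gmlvq import GMLVQModel
from .iterate import CVResult, IRMAResult
from .projector import Projector, build_projector

__all__ = [
    "save_model", "load_model",
    "save_subspace", "load_subspace",
    "save_basis", "load_basis",
]


def _arr(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def save_model(model: GMLVQModel, path) -> None:
    payload = {
        "kind": "gmlvq_model",
        "classes": [str(c) for c in model.classes],
        "prototypes": _arr(model.prototypes),
        "omega": _arr(model.omega),
        "training_trace": _arr(model.training_trace),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> GMLVQModel:
    payload = json.loads(Path(path).read_text())
    return GMLVQModel(
        prototypes=np.array(payload["prototypes"]),
        omega=np.array(payload["omega"]),
        classes=np.array(payload["classes"]),
        training_trace=list(payload["training_trace"]),
    )


def save_subspace(result: IRMAResult, path, classes=None) -> None:
    """Persist the accumulated subspace V together with the stopping curve."""
    payload = {
        "kind": "center_subspace",
        "n_features": int(result.vectors.shape[1]),
        "vectors": _arr(result.vectors),
        "converged": bool(result.converged),
        "chance_level": float(result.chance_level),
        "classes": [str(c) for c in classes] if classes is not None else None,
        "bac_curve": [
            {
                "mean_bac": r.mean_bac,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "per_class_recall": {str(k): float(v) for k, v in r.per_class_recall.items()},
            }
            for r in result.cv_results
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_subspace(path) -> IRMAResult:
    payload = json.loads(Path(path).read_text())
    cv_results = [
        CVResult(
            mean_bac=e["mean_bac"],
            ci_low=e["ci_low"],
            ci_high=e["ci_high"],
            fold_bacs=np.empty(0),
            per_class_recall=e["per_class_recall"],
        )
        for e in payload["bac_curve"]
    ]
    vectors = np.array(payload["vectors"], dtype=float).reshape(-1, payload["n_features"])
    return IRMAResult(
        vectors=vectors,
        cv_results=cv_results,
        models=[],
        converged=payload["converged"],
        chance_level=payload["chance_level"],
    )


def projector_from_subspace(result: IRMAResult) -> Projector:
    return build_projector(result.vectors, n_features=result.vectors.shape[1])


def save_basis(basis: PCABasis, path) -> None:
    payload = {
        "kind": "pca_basis",
        "components": _arr(basis.components),
        "reference_mean": _arr(basis.reference_mean),
        "variance_fractions": _arr(basis.variance_fractions),
        "zscore_mean": None if basis.zscore_mean is None else _arr(basis.zscore_mean),
        "zscore_sd": None if basis.zscore_sd is None else _arr(basis.zscore_sd),
        "mask_index": None if basis.mask_index is None else np.asarray(basis.mask_index).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_basis(path) -> PCABasis:
    payload = json.loads(Path(path).read_text())
    opt = lambda k: None if payload[k] is None else np.array(payload[k])
    return PCABasis(
        components=np.array(payload["components"]),
        reference_mean=np.array(payload["reference_mean"]),
        variance_fractions=np.array(payload["variance_fractions"]),
        zscore_mean=opt("zscore_mean"),
        zscore_sd=opt("zscore_sd"),
        mask_index=None if payload["mask_index"] is None else np.array(payload["mask_index"], dtype=int),
    )
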