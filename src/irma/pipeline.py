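"""End-to-end harmonization pipeline.

Controls (center-labeled) feed the iterative subspace extraction; the
resulting correction is applied to all feature vectors and to the training
of the subsequent disease classifier; diagnostics quantify the remaining
center signal and the overlap between disease model and center subspace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledFeatureSet
from .diagnostics import count_significant_features, principal_angles
from .gmlvq import TrainConfig, leading_eigenvectors, train_gmlvq
from .iterate import repeated_cv, run_irma
from .projector import harmonize_features

__all__ = ["RunConfig", "full_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run settings; defaults reproduce the reference protocol
    (10x10 repeated CV, 80% variance target, 30 epochs, steps 1 and 2)."""

    seed: int = 0
    repeats: int = 10
    folds: int = 10
    variance_target: float = 0.8
    max_iter: int | None = None
    alpha: float = 0.05
    train: TrainConfig = field(default_factory=TrainConfig)

    def stage_seed(self, stage: int) -> int:
        return int(np.random.SeedSequence([self.seed, stage]).generate_state(1)[0] % (2**31))


def _validate(controls: LabeledFeatureSet, patients: LabeledFeatureSet | None, config: RunConfig) -> None:
    _, counts = np.unique(controls.center, return_counts=True)
    if np.any(counts < config.folds):
        raise ValueError(
            f"smallest control center cohort ({int(counts.min())}) is below folds={config.folds}"
        )
    if patients is not None:
        if patients.disease is None:
            raise ValueError("patients must carry disease labels")
        _, dcounts = np.unique(patients.disease, return_counts=True)
        if np.any(dcounts < config.folds):
            raise ValueError(
                f"smallest disease cohort ({int(dcounts.min())}) is below folds={config.folds}"
            )


def full_pipeline(
    controls: LabeledFeatureSet,
    patients: LabeledFeatureSet | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Run subspace extraction, harmonization, disease training, diagnostics.

    Returns a report dict whose deterministic fields are identical across
    reruns with the same seed.  Input features are assumed to already live
    in the shared (PCA, z-scored) coordinate system.
    """
    config = config or RunConfig()
    _validate(controls, patients, config)

    logger.info("stage 1: iterative center-subspace extraction on %d controls", controls.n_samples)
    irma_result = run_irma(
        controls.features,
        controls.center,
        config.train,
        repeats=config.repeats,
        folds=config.folds,
        max_iter=config.max_iter,
        seed=config.stage_seed(1),
    )
    projector = irma_result.projector()
    report: dict = {
        "seed": config.seed,
        "subspace_dim": irma_result.n_iterations,
        "converged": irma_result.converged,
        "center_bac_curve": irma_result.bac_curve.tolist(),
        "irma": irma_result,
        "projector": projector,
    }

    logger.info("stage 2: harmonizing features (correction dim %d)", projector.dim)
    report["controls_harmonized"] = harmonize_features(controls.features, projector)

    n_uncorr, _ = count_significant_features(controls.features, controls.center, alpha=config.alpha)
    n_corr, _ = count_significant_features(
        report["controls_harmonized"], controls.center, alpha=config.alpha
    )
    report["significant_features_before"] = n_uncorr
    report["significant_features_after"] = n_corr

    if patients is not None:
        logger.info("stage 3: disease model under correction (%d patients)", patients.n_samples)
        report["patients_harmonized"] = harmonize_features(patients.features, projector)
        disease_cv = repeated_cv(
            patients.features,
            patients.disease,
            config.train,
            projector,
            repeats=config.repeats,
            folds=config.folds,
            seed=config.stage_seed(2),
        )
        report["disease_cv"] = disease_cv
        report["disease_bac"] = disease_cv.mean_bac
        model = train_gmlvq(patients.features, patients.disease, config.train, projector)
        report["disease_model"] = model
        if projector.dim > 0:
            _, d_basis = leading_eigenvectors(model.lambda_, 2)
            angles = principal_angles(d_basis, projector.vectors.T)
            report["disease_center_angles_deg"] = angles.angles_deg.tolist()
    return report
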