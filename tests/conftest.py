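import numpy as np
import pytest

from irma import TrainConfig, generate_multicenter, make_truth, run_irma

# One fixed reference study: 4 centers, 31 features, planted 3-D center
# subspace with 2-SD offsets, 30 controls/center, 3 diseases (35 patients
# each, one cohort per center) shifted 3 SD orthogonally to the center
# subspace.  The subspace extraction sees only the controls, so the same
# run serves every downstream experiment.
REFERENCE_SEED = 12345
CV_SEED = 7


@pytest.fixture(scope="session")
def reference_truth():
    return make_truth(seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def reference_data(reference_truth):
    return generate_multicenter(reference_truth)


@pytest.fixture(scope="session")
def reference_controls(reference_data):
    return reference_data.controls()


@pytest.fixture(scope="session")
def reference_patients(reference_data):
    mask = np.asarray([str(d) != "" for d in reference_data.disease])
    return reference_data.subset(mask)


@pytest.fixture(scope="session")
def reference_irma(reference_controls):
    """10x10 repeated-CV subspace extraction on the reference controls."""
    return run_irma(
        reference_controls.features,
        reference_controls.center,
        TrainConfig(),
        repeats=10,
        folds=10,
        seed=CV_SEED,
    )


@pytest.fixture(scope="session")
def two_gaussians():
    """Two 10-D unit-variance Gaussian classes 6 SD apart along axis 0."""
    rng = np.random.default_rng(0)
    n = 100
    X0 = rng.normal(0.0, 1.0, (n, 10))
    X1 = rng.normal(0.0, 1.0, (n, 10))
    X1[:, 0] += 6.0
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    return X, y
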