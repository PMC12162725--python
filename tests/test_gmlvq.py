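"""Unit tests for the prototype classifier with adaptive relevance matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irma import (
    GMLVQModel,
    TrainConfig,
    balanced_accuracy,
    build_projector,
    discriminative_projection,
    glvq_cost,
    leading_eigenvectors,
    normalize_omega,
    predict,
    relevance_distance,
    train_gmlvq,
)
from irma.gmlvq import InvalidModelError


class TestNormalizeOmega:
    def test_identity_scaled_to_unit_trace(self):
        out = normalize_omega(np.eye(2))
        np.testing.assert_allclose(out, np.eye(2) / np.sqrt(2))
        assert abs(np.trace(out.T @ out) - 1.0) < 1e-12

    def test_known_square_sum_is_halved(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0]])  # squared entries sum to 4
        np.testing.assert_allclose(normalize_omega(m), m / 2.0)

    def test_random_matrix_against_square_sum_oracle(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(5, 5))
        out = normalize_omega(m)
        # oracle: direct elementwise summation
        assert abs(sum(v**2 for v in out.ravel()) - 1.0) < 1e-12
        assert abs(np.trace(out.T @ out) - 1.0) < 1e-12

    def test_zero_matrix_rejected(self):
        with pytest.raises(InvalidModelError):
            normalize_omega(np.zeros((3, 3)))


class TestRelevanceDistance:
    @pytest.mark.parametrize(
        "x, w, lam, expected",
        [
            ((3.0, 4.0), (0.0, 0.0), np.eye(2), 25.0),  # Euclidean case
            ((1.5, -2.0), (1.5, -2.0), np.array([[2.0, 0.3], [0.3, 1.0]]), 0.0),
            ((2.0, 5.0), (0.0, 0.0), np.diag([1.0, 0.0]), 4.0),  # null direction ignored
        ],
    )
    def test_known_values(self, x, w, lam, expected):
        assert relevance_distance(np.array(x), np.array(w), lam) == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            relevance_distance(np.ones(3), np.ones(2), np.eye(3))


def _model(prototypes, omega, classes):
    return GMLVQModel(
        prototypes=np.asarray(prototypes, float),
        omega=np.asarray(omega, float),
        classes=np.asarray(classes),
    )


class TestCost:
    def test_equidistant_sample_contributes_zero(self):
        m = _model([[-1.0, 0.0], [1.0, 0.0]], np.eye(2) / np.sqrt(2), [0, 1])
        assert glvq_cost(m, np.array([[0.0, 5.0]]), np.array([0])) == pytest.approx(0.0)

    def test_sample_at_own_prototype_contributes_minus_one(self):
        m = _model([[-1.0, 0.0], [1.0, 0.0]], np.eye(2) / np.sqrt(2), [0, 1])
        assert glvq_cost(m, np.array([[-1.0, 0.0]]), np.array([0])) == pytest.approx(-1.0)

    def test_matches_term_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        W = rng.normal(size=(3, 4))
        omega = normalize_omega(rng.normal(size=(4, 4)))
        m = _model(W, omega, [0, 1, 2])
        X = rng.normal(size=(12, 4))
        y = rng.integers(0, 3, 12)
        # oracle: term-by-term using relevance_distance
        lam = omega.T @ omega
        expected = 0.0
        for xi, yi in zip(X, y):
            dists = [relevance_distance(xi, w, lam) for w in W]
            d_plus = dists[yi]
            d_minus = min(d for j, d in enumerate(dists) if j != yi)
            expected += (d_plus - d_minus) / (d_plus + d_minus)
        assert glvq_cost(m, X, y) == pytest.approx(expected, rel=1e-12)

    def test_missing_prototype_rejected(self):
        m = _model([[0.0], [1.0]], np.eye(1), [0, 1])
        with pytest.raises(InvalidModelError):
            glvq_cost(m, np.array([[0.5]]), np.array([2]))


class TestPredict:
    def test_sample_at_prototype(self):
        m = _model([[0.0, 0.0], [3.0, 3.0]], np.eye(2) / np.sqrt(2), [1, 2])
        assert predict(m, np.array([[3.0, 3.0]]))[0] == 2

    def test_tie_broken_toward_smallest_class(self):
        m = _model([[1.0, 0.0], [5.0, 5.0], [-1.0, 0.0]], np.eye(2) / np.sqrt(2), [1, 2, 3])
        assert predict(m, np.array([[0.0, 0.0]]))[0] == 1

    def test_matches_brute_force_nearest_prototype(self):
        rng = np.random.default_rng(21)
        W = rng.normal(size=(4, 6))
        omega = normalize_omega(rng.normal(size=(6, 6)))
        m = _model(W, omega, [0, 1, 2, 3])
        X = rng.normal(size=(50, 6))
        lam = omega.T @ omega
        expected = [
            int(np.argmin([relevance_distance(x, w, lam) for w in W])) for x in X
        ]
        np.testing.assert_array_equal(predict(m, X), expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 8))
    def test_brute_force_equivalence_property(self, seed, n_classes, n_features):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(n_classes, n_features))
        omega = normalize_omega(rng.normal(size=(n_features, n_features)))
        m = _model(W, omega, np.arange(n_classes))
        X = rng.normal(size=(30, n_features))
        lam = omega.T @ omega
        expected = [int(np.argmin([relevance_distance(x, w, lam) for w in W])) for x in X]
        np.testing.assert_array_equal(predict(m, X), expected)


class TestBalancedAccuracy:
    def test_perfect(self):
        assert balanced_accuracy([1, 2, 2], [1, 2, 2]) == 1.0

    def test_confusion_counts_by_hand(self):
        # confusion [[8, 2], [5, 5]] -> (0.8 + 0.5) / 2
        y_true = [0] * 10 + [1] * 10
        y_pred = [0] * 8 + [1] * 2 + [0] * 5 + [1] * 5
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.65)

    def test_constant_predictor_four_classes(self):
        y_true = np.repeat([0, 1, 2, 3], 5)
        assert balanced_accuracy(y_true, np.zeros(20, dtype=int)) == pytest.approx(0.25)


class TestLeadingEigenvectors:
    def test_diagonal_case(self):
        vals, vecs = leading_eigenvectors(np.diag([3.0, 1.0, 0.0]), 2)
        np.testing.assert_allclose(vals, [3.0, 1.0])
        np.testing.assert_allclose(np.abs(vecs), np.eye(3)[:, :2], atol=1e-12)
        assert np.all(vecs[np.argmax(np.abs(vecs), axis=0), [0, 1]] > 0)

    def test_rank_one_recovery(self):
        v = np.array([0.6, -0.8, 0.0])
        vals, vecs = leading_eigenvectors(np.outer(v, v), 1)
        assert vals[0] == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(vecs[:, 0]), np.abs(v), atol=1e-12)

    def test_against_power_iteration_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 6))
        lam = A.T @ A
        vals, vecs = leading_eigenvectors(lam, 1)
        v = rng.normal(size=6)
        for _ in range(3000):
            v = lam @ v
            v /= np.linalg.norm(v)
        assert abs(v @ lam @ v - vals[0]) < 1e-6
        assert abs(abs(v @ vecs[:, 0]) - 1.0) < 1e-6

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            leading_eigenvectors(np.array([[0.0, 1.0], [0.0, 0.0]]), 1)


class TestTraining:
    def test_separated_gaussians_learned_perfectly(self, two_gaussians):
        X, y = two_gaussians
        model = train_gmlvq(X, y, TrainConfig())
        assert balanced_accuracy(y, predict(model, X)) == 1.0
        assert model.training_trace[-1] <= model.training_trace[0]

    def test_relevance_concentrates_on_planted_axis(self, two_gaussians):
        X, y = two_gaussians
        model = train_gmlvq(X, y, TrainConfig())
        vals, vecs = leading_eigenvectors(model.lambda_, 1)
        assert vals[0] >= 0.9
        angle = np.degrees(np.arccos(min(abs(vecs[0, 0]), 1.0)))
        assert angle <= 10.0

    def test_projected_out_signal_gives_chance_performance(self, two_gaussians):
        X, y = two_gaussians
        proj = build_projector([np.eye(10)[0]])
        model = train_gmlvq(X, y, TrainConfig(), projector=proj)
        bac = balanced_accuracy(y, predict(model, X))
        assert abs(bac - 0.5) < 0.15
        # omega rows confined to the projector's range
        residual = model.omega @ (np.eye(10) - proj.matrix)
        assert np.max(np.abs(residual)) <= 1e-8

    def test_relevance_invariants_hold_after_training(self, two_gaussians):
        X, y = two_gaussians
        model = train_gmlvq(X, y, TrainConfig(epochs=5))
        lam = model.lambda_
        assert abs(np.trace(lam) - 1.0) < 1e-9
        np.testing.assert_allclose(lam, lam.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(lam)) > -1e-10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_gmlvq(np.ones((4, 2)), np.zeros(4), TrainConfig(epochs=1))


class TestDiscriminativeProjection:
    def test_known_coordinates(self, two_gaussians):
        X, y = two_gaussians
        model = train_gmlvq(X, y, TrainConfig())
        _, vecs = leading_eigenvectors(model.lambda_, 2)
        coords = discriminative_projection(model, vecs[:, 0][None, :])
        np.testing.assert_allclose(coords, [[1.0, 0.0]], atol=1e-9)

    def test_matches_inner_product_oracle(self, two_gaussians):
        X, y = two_gaussians
        model = train_gmlvq(X, y, TrainConfig())
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(7, 10))
        _, vecs = leading_eigenvectors(model.lambda_, 2)
        expected = np.array([[z @ vecs[:, 0], z @ vecs[:, 1]] for z in Z])
        np.testing.assert_allclose(discriminative_projection(model, Z), expected, atol=1e-12)
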