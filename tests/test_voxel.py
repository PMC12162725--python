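"""Unit tests for voxel-space reconstruction of corrected and removed profiles."""

import numpy as np
import pytest

from irma import (
    build_projector,
    corrected_image,
    extract_features,
    fit_reference_space,
    harmonize_features,
    reconstruct,
    removed_profile,
    voxel_profile,
    voxel_zscore,
)


@pytest.fixture()
def basis():
    rng = np.random.default_rng(20)
    return fit_reference_space(rng.normal(size=(30, 40)), 0.9)


@pytest.fixture()
def projector(basis):
    rng = np.random.default_rng(21)
    q, _ = np.linalg.qr(rng.normal(size=(basis.n_components, 3)))
    return build_projector(q.T)


class TestReconstruct:
    def test_zero_features_give_reference_mean(self, basis):
        np.testing.assert_allclose(reconstruct(np.zeros(basis.n_components), basis),
                                   basis.reference_mean)

    def test_unit_feature_adds_one_component(self, basis):
        x = np.eye(basis.n_components)[2]
        np.testing.assert_allclose(reconstruct(x, basis),
                                   basis.reference_mean + basis.components[:, 2], atol=1e-12)

    def test_round_trip_exact_inside_span(self, basis):
        rng = np.random.default_rng(22)
        X = basis.reference_mean + rng.normal(size=(4, basis.n_components)) @ basis.components.T
        back = reconstruct(extract_features(X, basis), basis)
        np.testing.assert_allclose(back, X, atol=1e-9)


class TestRemovedAndCorrected:
    def test_orthogonal_features_leave_nothing_removed(self, basis, projector):
        x = harmonize_features(np.random.default_rng(23).normal(size=basis.n_components),
                               projector)
        np.testing.assert_allclose(removed_profile(x, projector, basis), 0.0, atol=1e-10)

    def test_in_subspace_features_fully_removed(self, basis, projector):
        x = projector.vectors[0] * 2.5
        removed = removed_profile(x, projector, basis)
        np.testing.assert_allclose(removed, reconstruct(x, basis) - basis.reference_mean,
                                   atol=1e-10)
        np.testing.assert_allclose(corrected_image(x, projector, basis),
                                   basis.reference_mean, atol=1e-10)

    def test_identity_projector_changes_nothing(self, basis):
        proj = build_projector([], n_features=basis.n_components)
        x = np.random.default_rng(24).normal(size=basis.n_components)
        np.testing.assert_allclose(corrected_image(x, proj, basis), reconstruct(x, basis))

    def test_decomposition_identity(self, basis, projector):
        rng = np.random.default_rng(25)
        x = rng.normal(size=basis.n_components)
        p = voxel_profile(x, projector, basis)
        np.testing.assert_allclose(p.corrected + p.removed, p.original, atol=1e-9)

    def test_harmonize_then_reconstruct_equals_subtract_removed(self, basis, projector):
        rng = np.random.default_rng(26)
        x = rng.normal(size=basis.n_components)
        a = reconstruct(harmonize_features(x, projector), basis)
        b = reconstruct(x, basis) - removed_profile(x, projector, basis)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_correction_aligns_center_mean_profiles(self, basis):
        # planted center offsets inside a known feature subspace: corrected
        # group-mean profiles must be closer together than uncorrected ones
        rng = np.random.default_rng(27)
        k = basis.n_components
        q, _ = np.linalg.qr(rng.normal(size=(k, 2)))
        proj = build_projector(q.T)
        means = [rng.normal(size=2) @ q.T * 3.0 + rng.normal(size=k) * 0.05 for _ in range(4)]
        before, after = [], []
        for i in range(4):
            for j in range(i + 1, 4):
                before.append(np.max(np.abs(reconstruct(means[i], basis) - reconstruct(means[j], basis))))
                after.append(np.max(np.abs(corrected_image(means[i], proj, basis)
                                           - corrected_image(means[j], proj, basis))))
        assert max(after) < max(before)


class TestVoxelZscore:
    def test_reference_mean_maps_to_zero(self):
        rng = np.random.default_rng(28)
        ref = rng.normal(size=(15, 20))
        np.testing.assert_allclose(voxel_zscore(ref.mean(axis=0), ref), 0.0, atol=1e-12)

    def test_one_sd_above_mean_maps_to_one(self):
        rng = np.random.default_rng(29)
        ref = rng.normal(size=(15, 20))
        x = ref.mean(axis=0) + ref.std(axis=0, ddof=1)
        np.testing.assert_allclose(voxel_zscore(x, ref), 1.0, atol=1e-12)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(30)
        ref = rng.normal(size=(10, 8))
        x = rng.normal(size=8)
        expected = [(x[j] - ref[:, j].mean()) / ref[:, j].std(ddof=1) for j in range(8)]
        np.testing.assert_allclose(voxel_zscore(x, ref), expected, atol=1e-12)

    def test_zero_variance_voxels_become_zero(self):
        ref = np.ones((6, 3))
        ref[:, 0] = np.arange(6.0)
        z = voxel_zscore(np.array([1.0, 5.0, 5.0]), ref)
        assert z[1] == 0.0 and z[2] == 0.0
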