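"""Grad-CAM machinery: gradients, importance weights, maps, aggregation."""

import numpy as np
import pytest

from braincam.errors import DegenerateMapError, ShapeError, StateError
from braincam.explain import (
    FeatureStack,
    GrandAverageMap,
    ImportanceWeights,
    LocalizationMap,
    capture_features_and_gradients,
    grand_average,
    importance_weights,
    localization_map,
    receptive_field_geometry,
    standardize_map,
    subject_map,
    upsample_map,
)
from braincam.model import BlockSpec, NetConfig, RegressionNet


class TestImportanceWeights:
    def test_constant_gradient(self):
        g = FeatureStack(np.full((3, 2, 2, 2), 4.0))
        w = importance_weights(g)
        np.testing.assert_allclose(w.alpha, [4.0, 4.0, 4.0])

    def test_symmetric_gradient_cancels(self):
        m = np.ones((1, 2, 2, 2))
        m[0, :, :, 0] = -1.0
        assert importance_weights(FeatureStack(m)).alpha[0] == pytest.approx(0.0)

    def test_random_map_mean(self, rng):
        m = rng.normal(size=(1, 2, 2, 2))
        expected = m.sum() / 8.0  # (1/Z)·ΣΣΣ with Z = 8 units
        assert importance_weights(FeatureStack(m)).alpha[0] == pytest.approx(expected)


class TestLocalizationMap:
    def test_single_map_identity(self, rng):
        a = rng.normal(size=(1, 3, 3, 3))
        out = localization_map(FeatureStack(a), ImportanceWeights([1.0]))
        np.testing.assert_allclose(out.values, a[0])
        assert out.stage == "raw"

    def test_zero_weights(self, rng):
        a = rng.normal(size=(4, 3, 3, 3))
        out = localization_map(FeatureStack(a), ImportanceWeights(np.zeros(4)))
        assert np.all(out.values == 0.0)

    def test_hand_computed_combination(self, rng):
        a = rng.normal(size=(2, 2, 2, 2))
        out = localization_map(FeatureStack(a), ImportanceWeights([0.5, -2.0]))
        np.testing.assert_allclose(out.values, 0.5 * a[0] - 2.0 * a[1])

    def test_linearity(self, rng):
        a = rng.normal(size=(3, 2, 2, 2))
        w1, w2 = rng.normal(size=3), rng.normal(size=3)
        l1 = localization_map(FeatureStack(a), ImportanceWeights(w1)).values
        l2 = localization_map(FeatureStack(a), ImportanceWeights(w2)).values
        both = localization_map(FeatureStack(a), ImportanceWeights(w1 + w2)).values
        np.testing.assert_allclose(both, l1 + l2, atol=1e-12)

    def test_no_rectification_keeps_negative_values(self, rng):
        a = np.abs(rng.normal(size=(1, 3, 3, 3)))  # positive activations
        out = localization_map(FeatureStack(a), ImportanceWeights([-1.0]))
        assert out.values.min() < 0

    def test_length_mismatch(self, rng):
        with pytest.raises(ShapeError):
            localization_map(
                FeatureStack(rng.normal(size=(3, 2, 2, 2))), ImportanceWeights([1.0])
            )


class TestGradientCapture:
    def test_shapes_and_finiteness(self, toy_net, rng):
        x = rng.normal(size=(8, 8, 8))
        f, g = capture_features_and_gradients(toy_net, x, [50.0, 1.0])
        assert f.maps.shape == g.maps.shape
        assert f.n_maps == toy_net.config.blocks[-1].out_channels
        assert np.all(np.isfinite(g.maps))

    def test_gradients_match_finite_differences(self, toy_net, rng):
        """∂y/∂A from backprop vs central differences through the head."""
        x = rng.normal(size=(8, 8, 8))
        cov = np.array([[55.0, 0.0]])
        f, g = capture_features_and_gradients(toy_net, x, cov[0])
        a = f.maps[None].copy()
        check = np.random.default_rng(0)
        eps = 1e-5
        for _ in range(25):
            n = check.integers(a.shape[1])
            i, j, k = (check.integers(s) for s in a.shape[2:])
            a_p, a_m = a.copy(), a.copy()
            a_p[0, n, i, j, k] += eps
            a_m[0, n, i, j, k] -= eps
            fd = (
                toy_net.head_forward(a_p, cov)[0] - toy_net.head_forward(a_m, cov)[0]
            ) / (2 * eps)
            an = g.maps[n, i, j, k]
            assert an == pytest.approx(fd, rel=1e-3, abs=1e-9)

    def test_identity_head_closed_form(self, rng):
        """With an identity hidden stage, α_n = w_n/Z and L = (1/Z)·Σ w_n A^n."""
        cfg = NetConfig(
            blocks=[BlockSpec(3, 1, 4)], hidden_units=4, use_covariates=False,
            dropout_rate=0.0, input_shape=(6, 6, 6),
        )
        net = RegressionNet(cfg, seed=3, dtype=np.float64)
        # engineer the head: hidden = identity (weights I, bias 0), output = w·h + b
        net.fc_hidden.w.value = np.eye(4)
        net.fc_hidden.b.value = np.zeros(4)
        w_out = np.array([0.7, -1.2, 0.4, 2.0])
        net.fc_out.w.value = w_out[:, None]
        net.fc_out.b.value = np.array([0.3])
        x = rng.normal(size=(6, 6, 6))
        f, g = capture_features_and_gradients(net, x)
        z = f.z_units
        gap = f.maps.mean(axis=(1, 2, 3))
        assert np.all(gap > 0), "identity head requires positive pooled activations"
        alpha = importance_weights(g).alpha
        np.testing.assert_allclose(alpha, w_out / z, rtol=1e-10)
        expected_l = np.tensordot(w_out, f.maps, axes=1) / z
        got = localization_map(f, importance_weights(g)).values
        np.testing.assert_allclose(got, expected_l, atol=1e-6)


class TestUpsampleStandardize:
    def test_upsample_shape_and_stage(self, rng):
        raw = LocalizationMap(rng.normal(size=(6, 7, 6)))
        up = upsample_map(raw, (24, 28, 24))
        assert up.values.shape == (24, 28, 24)
        assert up.stage == "upsampled"

    def test_upsample_constant(self):
        raw = LocalizationMap(np.full((4, 4, 4), 3.0))
        up = upsample_map(raw, (16, 16, 16))
        interior = up.values[2:-2, 2:-2, 2:-2]
        assert np.max(np.abs(interior - 3.0)) < 1e-6

    def test_upsample_roundtrip_correlation(self, rng):
        from scipy import ndimage

        smooth = ndimage.gaussian_filter(rng.normal(size=(8, 8, 8)), 1.5)
        raw = LocalizationMap(smooth)
        up = upsample_map(raw, (32, 32, 32))
        down = ndimage.zoom(up.values, 0.25, order=3)
        r = np.corrcoef(smooth.ravel(), down.ravel())[0, 1]
        assert r > 0.95

    def test_receptive_field_geometry_even_dims(self):
        # window-3 stride-2 SAME pooling on even lengths: center(c) = 2c+1,
        # composed P times → step 2^P, offset 2^P − 1
        steps, offsets = receptive_field_geometry((32, 40, 32), 3)
        assert steps == [8, 8, 8] and offsets == [7, 7, 7]
        steps, offsets = receptive_field_geometry((16, 16, 16), 1)
        assert steps == [2, 2, 2] and offsets == [1, 1, 1]

    def test_rf_aligned_upsample_places_cell_at_center(self):
        raw = np.zeros((4, 5, 4))
        raw[1, 2, 1] = 1.0
        up = upsample_map(
            LocalizationMap(raw), (32, 40, 32), rf_geometry=([8, 8, 8], [7, 7, 7])
        )
        peak = np.unravel_index(np.argmax(up.values), up.values.shape)
        assert peak == (8 * 1 + 7, 8 * 2 + 7, 8 * 1 + 7)

    def test_upsample_wrong_stage(self, rng):
        m = LocalizationMap(rng.normal(size=(4, 4, 4)), stage="upsampled")
        with pytest.raises(StateError):
            upsample_map(m, (8, 8, 8))

    def test_standardize_moments(self, rng):
        m = LocalizationMap(rng.normal(2.0, 3.0, size=(8, 8, 8)), stage="upsampled")
        out = standardize_map(m)
        assert abs(out.values.mean()) < 1e-10
        assert out.values.std() == pytest.approx(1.0, abs=1e-10)
        assert out.stage == "standardized"

    def test_standardize_affine_invariance(self, rng):
        vals = rng.normal(size=(6, 6, 6))
        a = standardize_map(LocalizationMap(vals, stage="upsampled"))
        b = standardize_map(LocalizationMap(3.0 * vals + 11.0, stage="upsampled"))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_standardize_sign_flip(self, rng):
        vals = rng.normal(size=(6, 6, 6))
        a = standardize_map(LocalizationMap(vals, stage="upsampled"))
        b = standardize_map(LocalizationMap(-vals, stage="upsampled"))
        np.testing.assert_allclose(a.values, -b.values, atol=1e-9)

    def test_standardize_constant_map_degenerate(self):
        m = LocalizationMap(np.ones((4, 4, 4)), stage="upsampled")
        with pytest.raises(DegenerateMapError):
            standardize_map(m)


class TestGrandAverage:
    def _std_map(self, rng, shape=(8, 8, 8)):
        vals = rng.normal(size=shape)
        return standardize_map(LocalizationMap(vals, stage="upsampled"))

    def test_single_subject(self, rng):
        m = self._std_map(rng)
        ga = grand_average([m], threshold_sd=2.0)
        np.testing.assert_allclose(ga.values, m.values, atol=1e-9)
        assert ga.n_subjects == 1

    def test_mask_matches_brute_force_count(self, rng):
        maps = [self._std_map(rng) for _ in range(5)]
        ga = grand_average(maps, threshold_sd=2.0)
        assert int(ga.thresholded_mask.sum()) == int((np.abs(ga.values) > 2.0).sum())

    def test_cancellation_is_degenerate(self, rng):
        m = self._std_map(rng)
        neg = LocalizationMap(-m.values, stage="standardized")
        with pytest.raises(DegenerateMapError):
            grand_average([m, neg])

    def test_subject_order_invariance(self, rng):
        maps = [self._std_map(rng) for _ in range(6)]
        a = grand_average(maps)
        b = grand_average(list(reversed(maps)))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
        np.testing.assert_array_equal(a.thresholded_mask, b.thresholded_mask)

    def test_requires_standardized_stage(self, rng):
        with pytest.raises(StateError):
            grand_average([LocalizationMap(rng.normal(size=(4, 4, 4)), stage="raw")])


class TestSubjectPipeline:
    def test_full_pipeline_output(self, toy_net, rng):
        x = rng.normal(size=(8, 8, 8))
        m = subject_map(toy_net, x, [60.0, 1.0])
        assert m.values.shape == (8, 8, 8)
        assert m.stage == "standardized"
        assert abs(m.values.mean()) < 1e-8
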