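"""Separable-convolution operators against nested-loop oracles, and training."""

import numpy as np
import pytest

import hypercell as hc
from hypercell.scnn import samples_to_arrays


def _depthwise_oracle(x, kernels):
    """Four-nested-loop valid cross-correlation, one kernel per channel."""
    c, h, w = x.shape
    k = kernels.shape[1]
    out = np.zeros((c, h - k + 1, w - k + 1))
    for ch in range(c):
        for i in range(h - k + 1):
            for j in range(w - k + 1):
                out[ch, i, j] = np.sum(x[ch, i : i + k, j : j + k] * kernels[ch])
    return out


def _pointwise_oracle(x, weights, bias=None):
    """Per-pixel matrix multiply of the channel vector."""
    e = weights.shape[0]
    _, h, w = x.shape
    out = np.zeros((e, h, w))
    for i in range(h):
        for j in range(w):
            v = weights @ x[:, i, j]
            if bias is not None:
                v = v + bias
            out[:, i, j] = v
    return out


class TestDepthwiseConv:
    def test_all_ones_sums_window(self):
        out = hc.depthwise_conv(np.ones((1, 3, 3)), np.ones((1, 3, 3)))
        assert out.shape == (1, 1, 1) and out[0, 0, 0] == 9.0

    def test_unit_1x1_kernel_is_identity(self, rng):
        x = rng.normal(size=(3, 4, 4))
        np.testing.assert_array_equal(hc.depthwise_conv(x, np.ones((3, 1, 1))), x)

    @pytest.mark.parametrize("c,h,w,k", [(2, 5, 5, 3), (4, 8, 6, 3), (1, 7, 7, 5)])
    def test_matches_loop_oracle(self, rng, c, h, w, k):
        x = rng.normal(size=(c, h, w))
        kernels = rng.normal(size=(c, k, k))
        np.testing.assert_allclose(
            hc.depthwise_conv(x, kernels), _depthwise_oracle(x, kernels), rtol=1e-12
        )

    def test_kernel_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            hc.depthwise_conv(rng.normal(size=(2, 5, 5)), rng.normal(size=(3, 3, 3)))

    def test_oversized_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            hc.depthwise_conv(rng.normal(size=(1, 3, 3)), rng.normal(size=(1, 5, 5)))


class TestPointwiseConv:
    def test_constant_channels_sum(self):
        x = np.stack([np.full((3, 3), 2.0), np.full((3, 3), 3.0)])
        out = hc.pointwise_conv(x, np.array([[1.0, 1.0]]))
        np.testing.assert_array_equal(out, np.full((1, 3, 3), 5.0))

    def test_identity_matrix_is_identity(self, rng):
        x = rng.normal(size=(3, 4, 5))
        np.testing.assert_array_equal(hc.pointwise_conv(x, np.eye(3)), x)

    def test_matches_loop_oracle_with_bias(self, rng):
        x = rng.normal(size=(3, 4, 4))
        w = rng.normal(size=(2, 3))
        b = rng.normal(size=2)
        np.testing.assert_allclose(
            hc.pointwise_conv(x, w, b), _pointwise_oracle(x, w, b), rtol=1e-12
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            hc.pointwise_conv(rng.normal(size=(3, 4, 4)), rng.normal(size=(2, 4)))


class TestSeparableBlock:
    def test_identity_block(self, rng):
        x = rng.normal(size=(3, 5, 5))
        params = hc.SepConvParams(np.ones((3, 1, 1)), np.eye(3))
        np.testing.assert_array_equal(
            hc.separable_block(x, params, activation="identity"), x
        )

    def test_parameter_economy_closed_form(self):
        params = hc.SepConvParams(
            np.zeros((3, 3, 3)), np.zeros((8, 3))
        )
        assert params.param_count == 3 * 9 + 3 * 8 == 51
        assert params.standard_conv_param_count == 3 * 8 * 9 == 216

    def test_equals_composed_oracles(self, rng):
        x = rng.normal(size=(2, 6, 6))
        params = hc.SepConvParams(
            rng.normal(size=(2, 3, 3)), rng.normal(size=(4, 2)), rng.normal(size=4)
        )
        oracle = _pointwise_oracle(
            _depthwise_oracle(x, params.depthwise), params.pointwise, params.bias
        )
        np.testing.assert_allclose(
            hc.separable_block(x, params), np.maximum(oracle, 0.0), rtol=1e-12
        )

    def test_spatial_shrink_per_block(self):
        spec = hc.ClassifierSpec.for_patch(9, 8)
        spatial = 9
        for k, _e in spec.blocks:
            spatial -= k - 1
        assert spatial == 9 - 2 * 2  # two K=3 blocks


class TestBuildClassifier:
    def test_default_spec_outputs_three_scores(self, rng):
        model = hc.build_classifier(hc.ClassifierSpec.for_patch(9, 8), seed=0)
        out = model.forward(rng.normal(size=(2, 8, 9, 9)))
        assert out.shape == (2, 3)

    def test_same_seed_identical_parameters(self):
        a = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 4), seed=3)
        b = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 4), seed=3)
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa.depthwise, pb.depthwise)
            np.testing.assert_array_equal(pa.pointwise, pb.pointwise)
        np.testing.assert_array_equal(a.dense_w, b.dense_w)

    def test_oversized_block_spec_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            hc.ClassifierSpec(input_ws=3, input_bands=4, blocks=[(3, 8), (3, 8)])

    def test_ws1_spec_degenerates_to_pointwise(self):
        spec = hc.ClassifierSpec.for_patch(1, 8)
        assert all(k == 1 for k, _ in spec.blocks)

    def test_forward_equals_chained_operator_oracles(self, rng):
        spec = hc.ClassifierSpec.for_patch(7, 4)
        model = hc.build_classifier(spec, seed=1)
        x = rng.normal(size=(4, 7, 7))
        a = (x - model.input_mean[:, None, None]) / model.input_sd[:, None, None]
        for p in model.params:
            a = np.maximum(
                _pointwise_oracle(_depthwise_oracle(a, p.depthwise), p.pointwise, p.bias),
                0.0,
            )
        expected = a.mean(axis=(1, 2)) @ model.dense_w.T + model.dense_b
        np.testing.assert_allclose(model.forward(x[None])[0], expected, rtol=1e-9)


class TestTraining:
    def _tiny_samples(self, cube, mask, per_class, ws, seed=0):
        labeled = hc.sample_labeled_pixels(mask, per_class, seed=seed)
        return hc.make_pixel_samples(cube, labeled, ws)

    def test_memorizes_one_sample_per_class(self, zero_noise_cube, fast_config):
        _, cube, mask = zero_noise_cube
        samples = self._tiny_samples(cube, mask, 1, 5)
        model = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 8), seed=0)
        hc.train_classifier(model, samples, fast_config.replace(epochs=60))
        x, y = samples_to_arrays(samples)
        assert np.array_equal(model.predict(x), y)

    def test_loss_decreases_on_easy_task(self, easy_task_cube, fast_config):
        _, cube, mask = easy_task_cube
        samples = self._tiny_samples(cube, mask, 15, 5)
        model = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 8), seed=0)
        result = hc.train_classifier(model, samples, fast_config)
        assert result.loss_history[-1] < result.loss_history[0]

    def test_identical_seed_identical_history(self, easy_task_cube, fast_config):
        _, cube, mask = easy_task_cube
        samples = self._tiny_samples(cube, mask, 10, 5)
        histories = []
        for _ in range(2):
            model = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 8), seed=4)
            result = hc.train_classifier(model, samples, fast_config.replace(seed=4))
            histories.append(result.loss_history)
        assert histories[0] == histories[1]

    def test_empty_sample_list_rejected(self, fast_config):
        model = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 8), seed=0)
        with pytest.raises(ValueError):
            hc.train_classifier(model, [], fast_config)

    def test_save_load_round_trip(self, tmp_path, zero_noise_cube, fast_config, rng):
        _, cube, mask = zero_noise_cube
        samples = self._tiny_samples(cube, mask, 3, 5)
        model = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 8), seed=0)
        hc.train_classifier(model, samples, fast_config)
        model.save(tmp_path / "model.npz")
        back = hc.SCNNClassifier.load(tmp_path / "model.npz")
        x = rng.normal(size=(3, 8, 5, 5)) * 50 + 80
        np.testing.assert_array_equal(model.forward(x), back.forward(x))


class TestPredictMap:
    def test_scores_sum_to_one_and_shapes(self, zero_noise_cube, fast_config):
        _, cube, mask = zero_noise_cube
        labeled = hc.sample_labeled_pixels(mask, 5, seed=1)
        samples = hc.make_pixel_samples(cube, labeled, 5)
        model = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 8), seed=0)
        hc.train_classifier(model, samples, fast_config)
        pred, scores = hc.predict_map(model, cube, 5)
        assert pred.shape == mask.shape
        assert scores.shape == mask.shape + (3,)
        np.testing.assert_allclose(scores.sum(axis=2), 1.0, atol=1e-12)

    def test_constant_cube_single_class_map(self, fast_config, zero_noise_cube):
        _, cube, mask = zero_noise_cube
        labeled = hc.sample_labeled_pixels(mask, 5, seed=1)
        samples = hc.make_pixel_samples(cube, labeled, 5)
        model = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 8), seed=0)
        hc.train_classifier(model, samples, fast_config)
        flat = hc.HSCube(np.full((10, 10, 8), 40.0))
        pred, _ = hc.predict_map(model, flat, 5)
        assert len(np.unique(pred.labels)) == 1

    def test_band_mismatch_rejected(self, fast_config):
        model = hc.build_classifier(hc.ClassifierSpec.for_patch(5, 8), seed=0)
        with pytest.raises(ValueError):
            hc.predict_map(model, hc.HSCube(np.zeros((6, 6, 4))), 5)
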