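import numpy as np
import pytest

from usvdetect.features import melspec
from usvdetect.model import (
    HybridUsvModel,
    ModelConfig,
    load_checkpoint,
    predict,
    save_checkpoint,
    softmax_loss_and_grad,
    weighted_cross_entropy,
)


@pytest.fixture(scope="module")
def grad_check_config():
    return ModelConfig(context=4, bands=10, cnn_1d=((3, 2), (3, 1)),
                       cnn_2d=((3, 2), (3, 1)), lstm_hidden=3, fc_hidden=(4,),
                       class_weights=(0.7, 0.3), seed=0)


class TestCnnMask:
    def test_mask_column_shape_and_range(self, tiny_model):
        rng = np.random.default_rng(0)
        window = rng.normal(-10, 5, (124, 51))
        column, filtered = tiny_model.cnn_mask(window)
        assert column.shape == (124,)
        assert np.all(column >= 0) and np.all(column <= 1)

    def test_zero_weights_give_half_mask(self, tiny_model_config):
        model = HybridUsvModel(tiny_model_config)
        for name in model.params:
            if name.startswith(("c1.", "c2.")):
                model.params[name] = np.zeros_like(model.params[name])
        column, _ = model.cnn_mask(np.random.default_rng(1).normal(size=(124, 51)))
        np.testing.assert_allclose(column, 0.5, atol=1e-7)

    def test_filtered_window_is_elementwise_product(self, tiny_model):
        rng = np.random.default_rng(2)
        window = rng.normal(-5, 3, (124, 51))
        column, filtered = tiny_model.cnn_mask(window)
        np.testing.assert_allclose(filtered, window * column[:, None], rtol=1e-6)

    def test_wrong_shape_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.cnn_mask(np.zeros((124, 50)))

    def test_window_path_matches_full_map_path(self, tiny_model):
        """Per-window CNN equals the full-map pass at every frame."""
        rng = np.random.default_rng(3)
        n = 40
        feature_map = rng.normal(-10, 5, (124, n))
        padded = tiny_model.pad_map(feature_map)
        full_mask, _ = tiny_model.cnn_forward(padded[None])
        k = tiny_model.config.context
        for t in (0, 7, n - 1):
            window = padded[:, t : t + 2 * k + 1].astype(np.float64)
            column, _ = tiny_model.cnn_mask(window)
            np.testing.assert_allclose(column, full_mask[0, :, t], atol=1e-6)

    def test_cnn_stage_is_frame_local(self, tiny_model):
        """Perturbing the map outside a frame's 51-frame context leaves its
        mask column unchanged."""
        rng = np.random.default_rng(4)
        n = 120
        base = rng.normal(-10, 5, (124, n))
        perturbed = base.copy()
        t0 = 60
        k = tiny_model.config.context
        perturbed[:, : t0 - k] += rng.normal(0, 10, (124, t0 - k))
        perturbed[:, t0 + k + 1 :] += 5.0
        m1, _ = tiny_model.cnn_forward(tiny_model.pad_map(base)[None])
        m2, _ = tiny_model.cnn_forward(tiny_model.pad_map(perturbed)[None])
        np.testing.assert_allclose(m1[0, :, t0], m2[0, :, t0], atol=1e-6)
        assert not np.allclose(m1[0, :, t0 - k - 3], m2[0, :, t0 - k - 3], atol=1e-6)


class TestClassifySequence:
    def test_single_column_probabilities_sum_to_one(self, tiny_model):
        track = tiny_model.classify_sequence(np.random.default_rng(0).random((1, 124)))
        p = track.values[0]
        assert 0 <= p <= 1  # complement is the background probability

    def test_length_preserved(self, tiny_model):
        track = tiny_model.classify_sequence(np.random.default_rng(1).random((332, 124)))
        assert track.values.shape == (332,)

    def test_categorical_output_equals_half_thresholding(self, tiny_model):
        x = np.random.default_rng(2).random((50, 124))
        logits, _ = tiny_model.lstm_forward(x[None])
        categorical = logits[0].argmax(axis=1)
        track = tiny_model.classify_sequence(x)
        np.testing.assert_array_equal(categorical, (track.values >= 0.5).astype(int))

    def test_empty_sequence_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.classify_sequence(np.zeros((0, 124)))


class TestWeightedCrossEntropy:
    def test_perfect_prediction_gives_zero(self):
        labels = np.array([1, 0, 1])
        track = np.array([1.0, 0.0, 1.0])
        assert weighted_cross_entropy(track, labels, (0.75, 0.25)) == 0.0

    def test_uniform_half_prediction_closed_form(self):
        # labels half 1 half 0, weights (0.75, 0.25):
        # loss = mean(w) * ln 2 = 0.5 * ln 2
        labels = np.array([1, 0] * 10)
        track = np.full(20, 0.5)
        expected = 0.5 * np.log(2.0)
        assert np.isclose(weighted_cross_entropy(track, labels, (0.75, 0.25)), expected)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 50)
        track = np.clip(rng.random(50), 0.05, 0.95)
        l1 = weighted_cross_entropy(track, labels, (0.6, 0.4))
        l2 = weighted_cross_entropy(track, labels, (1.2, 0.8))
        assert np.isclose(l2, 2 * l1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.zeros(3), np.zeros(4), (0.5, 0.5))


class TestGradients:
    def test_backprop_matches_numerical_gradients(self, grad_check_config):
        """End-to-end analytic gradients agree with central differences."""
        cfg = grad_check_config
        model = HybridUsvModel(cfg, dtype=np.float64)
        rng = np.random.default_rng(0)
        B, F, T = 2, cfg.bands, 6
        x = rng.standard_normal((B, F, T + 2 * cfg.context))
        y = rng.integers(0, 2, (B, T))

        def loss():
            mask, _ = model.cnn_forward(x)
            logits, _ = model.lstm_forward(mask.transpose(0, 2, 1))
            return softmax_loss_and_grad(logits, y, cfg.class_weights)[0]

        mask, cc = model.cnn_forward(x, want_cache=True)
        logits, sc = model.lstm_forward(mask.transpose(0, 2, 1), want_cache=True)
        _, dlogits = softmax_loss_and_grad(logits, y, cfg.class_weights)
        dmask_seq, seq_grads = model.lstm_backward(dlogits, sc)
        _, cnn_grads = model.cnn_backward(dmask_seq.transpose(0, 2, 1), cc)
        grads = {**seq_grads, **cnn_grads}
        for name, p in model.params.items():
            flat = p.reshape(-1)
            g = grads[name].reshape(-1)
            for j in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps = 1e-6
                orig = flat[j]
                flat[j] = orig + eps
                lp = loss()
                flat[j] = orig - eps
                lm = loss()
                flat[j] = orig
                num = (lp - lm) / (2 * eps)
                assert np.isclose(num, g[j], rtol=1e-4, atol=1e-7), name


class TestPredict:
    def test_shapes_track_spectrogram(self, tiny_model, tone_spec):
        track, mask = predict(tone_spec, tiny_model)
        assert track.values.shape == (tone_spec.n_frames,)
        assert mask.values.shape == (124, tone_spec.n_frames)
        assert np.all((track.values >= 0) & (track.values <= 1))
        assert np.all((mask.values >= 0) & (mask.values <= 1))

    def test_per_frame_probabilities_normalized(self, tiny_model):
        x = np.random.default_rng(5).random((20, 124))
        logits, _ = tiny_model.lstm_forward(x[None])
        z = logits[0].astype(np.float64)
        p = np.exp(z - z.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_segmented_and_single_pass_masks_agree(self, tiny_model, tone_spec):
        """Splitting inference into 1 s segments leaves the (frame-local)
        CNN mask identical; only the BiLSTM context changes."""
        _, mask_seg = predict(tone_spec, tiny_model, segment_len=111)
        _, mask_one = predict(tone_spec, tiny_model, segment_len=10_000)
        np.testing.assert_allclose(mask_seg.values, mask_one.values, atol=1e-7)


class TestReproducibility:
    def test_same_seed_same_weights_and_outputs(self, tiny_model_config):
        m1 = HybridUsvModel(tiny_model_config)
        m2 = HybridUsvModel(tiny_model_config)
        for name in m1.params:
            np.testing.assert_array_equal(m1.params[name], m2.params[name])
        x = np.random.default_rng(0).random((30, 124))
        np.testing.assert_array_equal(
            m1.classify_sequence(x).values, m2.classify_sequence(x).values
        )

    def test_checkpoint_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        back = load_checkpoint(path)
        assert back.config == tiny_model.config
        x = np.random.default_rng(1).random((20, 124))
        np.testing.assert_allclose(
            back.classify_sequence(x).values,
            tiny_model.classify_sequence(x).values,
            atol=1e-7,
        )


class TestConfigValidation:
    def test_class_weights_normalized(self):
        cfg = ModelConfig(class_weights=(3.0, 1.0))
        assert np.isclose(sum(cfg.class_weights), 1.0)
        assert np.isclose(cfg.class_weights[0], 0.75)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(class_weights=(0.0, 1.0))

    def test_context_too_small_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(context=0)
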