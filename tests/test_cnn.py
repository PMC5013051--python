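"""Network architecture, initialization, augmentation and training."""

import numpy as np
import pytest

from semgkit import _net, cnn
from semgkit.types import WindowSet


def _proxy_windows(n_per, n_classes=8, t=15, c=10, noise=0.2, seed=0, separation=4.0):
    """Envelope-like class patterns as raw windows."""
    rng = np.random.default_rng(seed)
    patterns = 1.0 + separation * rng.uniform(0, 1, size=(n_classes, c))
    X = np.concatenate(
        [np.tile(p, (n_per, t, 1)) + noise * rng.standard_normal((n_per, t, c)) for p in patterns]
    )
    y = np.repeat(np.arange(n_classes), n_per)
    return X, y


class TestArchitecture:
    def test_canonical_electrode_setups_reproduce_b4_sizes(self):
        s10 = cnn.build_network((15, 10), 51)
        assert s10.k4 == 5 and s10.k4_canonical
        assert s10.layer_shapes[-1] == ("b5_conv", (1, 1, 51))
        s12 = cnn.build_network((29, 12), 51)
        assert s12.k4 == 9 and s12.k4_canonical

    def test_channel_axis_collapses_in_first_block(self):
        shapes = dict(cnn.infer_shapes((15, 10), 51))
        assert shapes["b1_conv"] == (15, 1, 32)
        assert shapes["b2_pool"] == (5, 1, 32)
        assert shapes["b5_conv"] == (1, 1, 51)

    def test_pre_classifier_map_is_one_by_one_for_any_admissible_input(self):
        for t in (6, 15, 29, 30, 60):
            spec = cnn.build_network((t, 8), 12)
            assert dict(spec.layer_shapes)["b4_conv"][:2] == (1, 1)
            assert spec.k4 == (t - 3) // 3 + 1

    def test_parameter_count_matches_hand_tally(self):
        spec = cnn.build_network((15, 10), 51)
        by_hand = (
            (32 * 10 + 32)            # B1: full-row filters
            + (32 * 32 * 3 + 32)      # B2: 3-wide conv
            + (64 * 32 * 5 + 64)      # B3: 5-wide conv
            + (64 * 64 * 5 + 64)      # B4: k4 = 5
            + (51 * 64 * 1 + 51)      # B5: 1x1 classifier
        )
        assert spec.parameter_count() == by_hand

    def test_inadmissible_input_names_failing_block(self):
        with pytest.raises(ValueError, match="b2_pool"):
            cnn.build_network((2, 4), 5)
        with pytest.raises(ValueError, match="b5_conv"):
            cnn.build_network((15, 4), 1)


class TestInit:
    def test_fraction_zero_gives_all_zero_weights(self):
        spec = cnn.build_network((15, 4), 3)
        params = cnn.init_weights(spec, data_range=2.0, fraction=0.0, seed=0)
        assert all(np.all(v == 0) for v in params.values())

    def test_same_seed_reproduces_parameters(self):
        spec = cnn.build_network((15, 4), 3)
        a = cnn.init_weights(spec, 2.0, 0.05, seed=4)
        b = cnn.init_weights(spec, 2.0, 0.05, seed=4)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_weights_uniform_within_stated_bounds(self):
        spec = cnn.build_network((15, 10), 51)
        fraction, data_range = 0.05, 4.0
        params = cnn.init_weights(spec, data_range, fraction, seed=1)
        bound = fraction * data_range
        for name, v in params.items():
            if name.endswith("_W"):
                assert v.min() >= -bound and v.max() <= bound
                # draws actually fill the range
                assert v.max() > 0.8 * bound and v.min() < -0.8 * bound

    def test_nonpositive_data_range_rejected(self):
        spec = cnn.build_network((15, 4), 3)
        with pytest.raises(ValueError):
            cnn.init_weights(spec, 0.0, 0.01, seed=0)

    def test_scale_aware_init_zeroes_classifier_layer(self):
        spec = cnn.build_network((15, 4), 3)
        params = cnn.init_weights_scale_aware(spec, 5.0, seed=0)
        assert np.all(params["b5_conv_W"] == 0)
        assert np.any(params["b2_conv_W"] != 0)


class TestAugmentation:
    @pytest.fixture()
    def windows(self):
        rng = np.random.default_rng(12)
        n = 1000
        return WindowSet(
            samples=rng.uniform(0.5, 4.0, size=(n, 15, 4)),
            labels=rng.integers(0, 6, n),
            repetitions=rng.integers(1, 7, n),
            t_start=np.arange(n, dtype=float),
            sampling_rate=100.0,
        )

    def test_doubling_preserves_originals_and_label_multiset(self, windows):
        out = cnn.augment_gaussian(windows, cnn.AugmentationConfig(seed=0))
        assert out.n_windows == 2 * windows.n_windows
        assert np.array_equal(out.samples[: windows.n_windows], windows.samples)
        a = np.bincount(windows.labels)
        assert np.array_equal(np.bincount(out.labels), 2 * a)

    def test_realized_snr_within_half_db_of_25(self, windows):
        out = cnn.augment_gaussian(windows, cnn.AugmentationConfig(seed=3))
        n = windows.n_windows
        noise = out.samples[n:] - windows.samples
        sig_p = np.mean(windows.samples**2, axis=(1, 2))
        noise_p = np.mean(noise**2, axis=(1, 2))
        snr_db = 10 * np.log10(sig_p / noise_p)
        assert np.all(np.abs(snr_db - 25.0) <= 0.5)

    def test_factor_one_is_identity(self, windows):
        out = cnn.augment_gaussian(windows, cnn.AugmentationConfig(duplication_factor=1))
        assert out is windows

    def test_zero_power_window_copied_unperturbed(self):
        ws = WindowSet(
            samples=np.zeros((3, 8, 2)),
            labels=np.arange(3),
            repetitions=np.ones(3, dtype=int),
            t_start=np.zeros(3),
            sampling_rate=100.0,
        )
        out = cnn.augment_gaussian(ws, cnn.AugmentationConfig(seed=1))
        assert np.all(out.samples == 0)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        X, y = _proxy_windows(n_per=20, n_classes=5)
        spec = cnn.build_network((15, 10), 5)
        # batch size sized to the 100-window set so each epoch takes
        # several smooth momentum steps
        cfg = cnn.TrainingConfig(epochs=10, batch_size=32, seed=0)
        model, history = cnn.train_cnn(spec, (X, y), cfg)
        assert history[-1] < history[0]
        assert np.mean(cnn.predict_cnn(model, X).argmax(1) == y) > 0.9

    def test_zero_learning_rate_leaves_parameters_at_init(self):
        X, y = _proxy_windows(n_per=5, n_classes=3)
        spec = cnn.build_network((15, 10), 3)
        cfg = cnn.TrainingConfig(epochs=2, learning_rate=0.0, seed=5)
        model, _ = cnn.train_cnn(spec, (X, y), cfg)
        reference = cnn.init_weights_scale_aware(
            spec, float(X.max() - X.min()),
            seed=int(np.random.default_rng(5).integers(2**31)),
            hidden_gain=cfg.init_hidden_gain,
        )
        assert all(np.array_equal(model.params[k], reference[k]) for k in reference)

    def test_training_is_bit_reproducible(self):
        X, y = _proxy_windows(n_per=10, n_classes=4, seed=3)
        spec = cnn.build_network((15, 10), 4)
        m1, h1 = cnn.train_cnn(spec, (X, y), cnn.TrainingConfig(epochs=3, seed=11))
        m2, h2 = cnn.train_cnn(spec, (X, y), cnn.TrainingConfig(epochs=3, seed=11))
        assert h1 == h2
        assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)

    def test_out_of_range_labels_rejected_before_training(self):
        X, y = _proxy_windows(n_per=4, n_classes=4)
        spec = cnn.build_network((15, 10), 3)  # labels reach 3 -> out of range
        with pytest.raises(ValueError, match="labels"):
            cnn.train_cnn(spec, (X, y), cnn.TrainingConfig(epochs=1))

    def test_window_shape_mismatch_rejected(self):
        X, y = _proxy_windows(n_per=4, t=20)
        spec = cnn.build_network((15, 10), 8)
        with pytest.raises(ValueError, match="shape"):
            cnn.train_cnn(spec, (X, y), cnn.TrainingConfig(epochs=1))

    def test_augmentation_does_not_hurt_by_more_than_two_points(self):
        """Median accuracy over 5 seeds: augmented training is no worse
        than plain training by more than 2 accuracy points."""
        spec = cnn.build_network((15, 10), 8)
        Xte, yte = _proxy_windows(n_per=12, noise=0.6, seed=1234)
        deltas = []
        for s in range(5):
            Xtr, ytr = _proxy_windows(n_per=20, noise=0.6, seed=100 + s)
            ws = WindowSet(
                samples=Xtr, labels=ytr,
                repetitions=np.ones_like(ytr), t_start=np.arange(ytr.size, dtype=float),
                sampling_rate=100.0,
            )
            aug = cnn.augment_gaussian(ws, cnn.AugmentationConfig(seed=s))
            cfg = cnn.TrainingConfig(epochs=4, seed=s)
            m_plain, _ = cnn.train_cnn(spec, (Xtr, ytr), cfg)
            m_aug, _ = cnn.train_cnn(spec, aug, cfg)
            acc_plain = np.mean(cnn.predict_cnn(m_plain, Xte).argmax(1) == yte)
            acc_aug = np.mean(cnn.predict_cnn(m_aug, Xte).argmax(1) == yte)
            deltas.append(100 * (acc_aug - acc_plain))
        assert np.median(deltas) >= -2.0


class TestPrediction:
    def test_probability_rows_sum_to_one(self):
        X, y = _proxy_windows(n_per=6, n_classes=4)
        spec = cnn.build_network((15, 10), 4)
        model, _ = cnn.train_cnn(spec, (X, y), cnn.TrainingConfig(epochs=1, seed=0))
        probs = cnn.predict_cnn(model, X)
        assert probs.shape == (X.shape[0], 4)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_inputs_get_identical_rows(self):
        X, y = _proxy_windows(n_per=3, n_classes=3)
        spec = cnn.build_network((15, 10), 3)
        model, _ = cnn.train_cnn(spec, (X, y), cnn.TrainingConfig(epochs=1, seed=2))
        probs = cnn.predict_cnn(model, np.stack([X[0], X[0]]))
        np.testing.assert_allclose(probs[0], probs[1], rtol=1e-12)

    def test_zero_initialized_network_is_uniform(self):
        spec = cnn.build_network((15, 10), 7)
        params = cnn.init_weights(spec, 1.0, 0.0, seed=0)
        probs = cnn.predict_cnn(cnn.CNNModel(spec, params), np.ones((4, 15, 10)))
        np.testing.assert_allclose(probs, 1.0 / 7, atol=1e-12)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        spec = cnn.build_network((15, 4), 3)
        params = cnn.init_weights(spec, 2.0, 0.1, seed=1)
        model = cnn.CNNModel(spec, params)
        x = rng.standard_normal((4, 15, 4))
        y = rng.integers(0, 3, 4)
        logits, cache = model.forward(x, with_cache=True)
        _, dlog = _net.softmax_cross_entropy(logits, y)
        grads = model.backward(cache, dlog)
        eps = 1e-6
        for name, p in params.items():
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = _net.softmax_cross_entropy(model.forward(x), y)
                flat[i] = orig - eps
                lm, _ = _net.softmax_cross_entropy(model.forward(x), y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[i] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_model_save_load_round_trip(self, tmp_path):
        X, y = _proxy_windows(n_per=4, n_classes=3)
        spec = cnn.build_network((15, 10), 3)
        model, _ = cnn.train_cnn(spec, (X, y), cnn.TrainingConfig(epochs=1, seed=0))
        cnn.save_model(model, tmp_path / "net")
        back = cnn.load_model(tmp_path / "net")
        assert back.spec.k4 == model.spec.k4
        np.testing.assert_array_equal(cnn.predict_cnn(back, X), cnn.predict_cnn(model, X))
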