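"""Architecture construction, the training protocol, feature extraction."""

import numpy as np
import pytest

import seednet as sn
from seednet.deep_models import build_model, load_checkpoint, save_checkpoint
from seednet.nn import Conv1d, Dense, ResidualBlock, InceptionBlock


def _forward(model, n=3, b=200):
    x = np.random.default_rng(0).normal(0.5, 0.1, (n, 1, b)).astype(np.float32)
    return model.predict_proba(x)


class TestBuilders:
    def test_vgg_layer_sequence(self):
        model = sn.build_vgg(200, 4, seed=0)
        kinds = [
            (name, type(layer).__name__) for name, layer in model.layers.items()
        ]
        expected = [
            ("v1a_conv", "Conv1d"), ("v1a_bn", "BatchNorm"), ("v1a_elu", "ELU"),
            ("v1b_conv", "Conv1d"), ("v1b_bn", "BatchNorm"), ("v1b_elu", "ELU"),
            ("pool1", "MaxPool1d"),
            ("v2a_conv", "Conv1d"), ("v2a_bn", "BatchNorm"), ("v2a_elu", "ELU"),
            ("v2b_conv", "Conv1d"), ("v2b_bn", "BatchNorm"), ("v2b_elu", "ELU"),
            ("pool2", "MaxPool1d"),
            ("flatten", "Flatten"),
            ("fc1", "Dense"), ("fc1_bn", "BatchNorm"), ("fc1_elu", "ELU"),
            ("fc2", "Dense"),
        ]
        assert kinds == expected
        convs = [l for l in model.layers.values() if isinstance(l, Conv1d)]
        assert [c.cout for c in convs] == [16, 16, 32, 32]
        assert all(c.k == 3 for c in convs)
        assert model.layers["fc1"].w.shape == (64, 1600)  # 32 * (200 // 4)
        assert model.layers["fc2"].w.shape == (4, 64)

    def test_res_filter_schedule_doubles(self):
        model = sn.build_res(200, 4, seed=0)
        blocks = [l for l in model.layers.values() if isinstance(l, ResidualBlock)]
        assert [b.conv1.cout for b in blocks] == [32, 64, 128, 256]
        assert model.layers["stem_conv"].k == 7
        assert model.layers["stem_conv"].cout == 32
        assert model.layers["fc1"].w.shape == (4, 256)

    def test_inception_block_schedule_and_tail(self):
        model = sn.build_inception(200, 5, seed=0)
        blocks = [l for l in model.layers.values() if isinstance(l, InceptionBlock)]
        assert [b.out_channels for b in blocks] == [64, 128, 256, 512]
        assert model.layers["stem_conv"].cout == 16
        assert model.layers["stem_conv"].k == 3
        # a pooling layer follows every inception block except the last
        names = list(model.layers)
        assert "incpool1" in names and "incpool3" in names and "incpool4" not in names
        assert model.layers["fc1"].w.shape == (5, 512)

    @pytest.mark.parametrize("builder", [sn.build_vgg, sn.build_res, sn.build_inception])
    def test_output_is_probability_simplex(self, builder):
        proba = _forward(builder(200, 4, seed=1))
        assert proba.shape == (3, 4)
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("builder", [sn.build_vgg, sn.build_res, sn.build_inception])
    def test_forward_shape_trace_matches_hand_arithmetic(self, builder):
        b = 200
        model = builder(b, 4, seed=0)
        x = np.zeros((2, 1, b), dtype=np.float32)
        h = x
        shapes = {}
        for name, layer in model.layers.items():
            h = layer.forward(h, train=False)
            shapes[name] = h.shape
        if builder is sn.build_vgg:
            assert shapes["pool1"] == (2, 16, 100)
            assert shapes["pool2"] == (2, 32, 50)
            assert shapes["flatten"] == (2, 1600)
        elif builder is sn.build_res:
            assert shapes["stem_pool"] == (2, 32, 100)
            assert shapes["res4"] == (2, 256, 100)
            assert shapes["flatten"] == (2, 256)
        else:
            assert shapes["stem_pool"] == (2, 16, 100)
            assert shapes["inc1"] == (2, 64, 100)
            assert shapes["inc2"] == (2, 128, 50)
            assert shapes["inc4"] == (2, 512, 12)
            assert shapes["flatten"] == (2, 512)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="input_len"):
            sn.build_vgg(4, 3)


class TestTrain:
    def test_separable_three_class_benchmark(self, trained_tiny_vgg):
        _, fit, _, _ = trained_tiny_vgg
        assert fit.test_accuracy >= 0.98

    def test_single_epoch_bookkeeping(self, tiny_separable):
        data, split = tiny_separable
        model = sn.build_vgg(data.n_bands, data.n_classes, seed=0)
        fit = sn.train(model, data, split, sn.TrainConfig(epochs=1, seed=0))
        assert len(fit.history) == 1
        assert fit.best_epoch == 1
        assert set(fit.history[0]) == {"epoch", "train_loss", "train_acc", "val_acc"}

    def test_same_seed_reproduces_history_and_confusion(self, tiny_separable):
        data, split = tiny_separable
        runs = []
        for _ in range(2):
            model = sn.build_vgg(data.n_bands, data.n_classes, seed=5)
            runs.append(
                sn.train(model, data, split,
                         sn.TrainConfig(epochs=3, batch_size=16, seed=5))
            )
        assert runs[0].history == runs[1].history
        assert np.array_equal(runs[0].confusion, runs[1].confusion)

    def test_zero_learning_rate_leaves_weights_unchanged(self, tiny_separable):
        data, split = tiny_separable
        model = sn.build_vgg(data.n_bands, data.n_classes, seed=0)
        before = model.state_dict()
        sn.train(model, data, split,
                 sn.TrainConfig(learning_rate=0.0, epochs=2, seed=0))
        after = model.state_dict()
        assert before.keys() == after.keys()
        for k in before:
            assert np.array_equal(before[k], after[k]), k


class TestEvaluate:
    def test_perfect_and_constant_predictors(self, trained_tiny_vgg):
        model, _, data, split = trained_tiny_vgg
        acc, confusion = sn.evaluate(model, data, split.test_idx)
        assert confusion.sum() == len(split.test_idx)
        counts = np.bincount(data.labels[split.test_idx], minlength=data.n_classes)
        assert np.array_equal(confusion.sum(axis=1), counts)
        assert acc == pytest.approx(np.trace(confusion) / len(split.test_idx))

    def test_accuracy_matches_brute_force_match_fraction(self, trained_tiny_vgg):
        model, _, data, split = trained_tiny_vgg
        idx = split.test_idx
        x = np.ascontiguousarray(data.spectra[idx][:, None, :], dtype=np.float32)
        pred = model.predict_proba(x).argmax(axis=1)
        expected = float(np.mean([p == t for p, t in zip(pred, data.labels[idx])]))
        acc, _ = sn.evaluate(model, data, idx)
        assert acc == pytest.approx(expected)

    def test_empty_index_set_rejected(self, trained_tiny_vgg):
        model, _, data, _ = trained_tiny_vgg
        with pytest.raises(ValueError):
            sn.evaluate(model, data, np.array([], dtype=int))


class TestExtractFeatures:
    def test_fc2_rows_sum_to_one(self, trained_tiny_vgg):
        model, _, data, split = trained_tiny_vgg
        feats = sn.extract_features(model, "Fc2", data, split.test_idx[:10])
        np.testing.assert_allclose(feats.sum(axis=1), 1.0, atol=1e-6)

    def test_flatten_width_matches_shape_arithmetic(self, trained_tiny_vgg):
        model, _, data, split = trained_tiny_vgg
        feats = sn.extract_features(model, "flatten", data, split.test_idx[:4])
        assert feats.shape == (4, 32 * (data.n_bands // 4))

    def test_duplicate_inputs_give_identical_features(self, trained_tiny_vgg):
        model, _, data, split = trained_tiny_vgg
        i = int(split.test_idx[0])
        feats = sn.extract_features(model, "Fc1", data, np.array([i, i, i]))
        assert np.array_equal(feats[0], feats[1])
        assert np.array_equal(feats[1], feats[2])

    def test_unknown_layer_lists_valid_names(self, trained_tiny_vgg):
        model, _, data, split = trained_tiny_vgg
        with pytest.raises(KeyError, match="Fc1"):
            sn.extract_features(model, "conv9", data, split.test_idx[:2])


def test_checkpoint_round_trip(tmp_path, trained_tiny_vgg):
    model, _, data, split = trained_tiny_vgg
    path = save_checkpoint(model, tmp_path / "vgg.npz")
    back = load_checkpoint(path)
    assert back.spec == model.spec
    a = model.state_dict()
    b = back.state_dict()
    assert a.keys() == b.keys()
    for k in a:
        assert np.array_equal(a[k], b[k]), k
    idx = split.test_idx[:8]
    x = np.ascontiguousarray(data.spectra[idx][:, None, :], dtype=np.float32)
    np.testing.assert_array_equal(model.predict_proba(x), back.predict_proba(x))
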