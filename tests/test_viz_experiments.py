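"""t-SNE embeddings, classification maps, and the comparison/sweep harness."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

import seednet as sn
from seednet.experiments import run_comparison, run_size_sweep
from seednet.viz import render_class_map, tsne_layers


class TestTsneLayers:
    def test_duplicates_colocate_and_seed_reproduces(self, trained_tiny_vgg):
        model, _, data, split = trained_tiny_vgg
        base = split.test_idx[:10]
        idx = np.concatenate([base, base])  # every point duplicated
        res = tsne_layers(model, data, idx, layers=["flatten"],
                          perplexity=5.0, seed=0)[0]
        diameter = np.ptp(res.coords, axis=0).max()
        for i in range(10):
            d = np.linalg.norm(res.coords[i] - res.coords[i + 10])
            assert d < 0.05 * diameter
        res2 = tsne_layers(model, data, idx, layers=["flatten"],
                           perplexity=5.0, seed=0)[0]
        np.testing.assert_array_equal(res.coords, res2.coords)

    def test_separated_classes_give_clustered_embedding(self, trained_tiny_vgg):
        model, _, data, split = trained_tiny_vgg
        idx = split.test_idx
        res = tsne_layers(model, data, idx, layers=["Fc1"],
                          perplexity=8.0, seed=0)[0]
        assert silhouette_score(res.coords, res.sample_labels) > 0.5

    def test_raw_layer_needs_no_model(self, tiny_separable):
        data, split = tiny_separable
        res = tsne_layers(None, data, split.test_idx, layers=["raw"],
                          perplexity=5.0, seed=1)[0]
        assert res.coords.shape == (len(split.test_idx), 2)
        assert np.all(np.isfinite(res.coords))

    def test_too_few_samples_for_perplexity(self, tiny_separable):
        data, split = tiny_separable
        with pytest.raises(ValueError, match="perplexity"):
            tsne_layers(None, data, split.test_idx[:10], layers=["raw"],
                        perplexity=30.0, seed=0)


class TestRenderClassMap:
    def _scene(self, n_seeds=5, seed=0):
        cfg = sn.SceneGeneratorConfig(n_seeds=n_seeds, image_size=(80, 80), seed=seed)
        triplet, mask, classes, _ = sn.generate_scene(cfg)
        return sn.calibrate(triplet), mask, classes

    def test_single_seed_takes_palette_color(self):
        cube, mask, _ = self._scene(n_seeds=1)
        cm = render_class_map(cube, mask, {1: 0})
        from seednet.viz import DEFAULT_PALETTE

        seed_px = cm.image[mask.labels == 1]
        assert np.all(seed_px == np.array(DEFAULT_PALETTE[0]))
        bg = cm.image[mask.labels == 0]
        assert np.all(bg[:, 0] == bg[:, 1])  # background stays gray

    def test_label_permutation_invariance(self):
        cube, mask, classes = self._scene(n_seeds=4, seed=3)
        preds = {k: int(classes[k - 1]) for k in range(1, 5)}
        a = render_class_map(cube, mask, preds)
        # permute label ids and permute predictions to match
        perm = {1: 3, 2: 4, 3: 1, 4: 2}
        labels2 = np.zeros_like(mask.labels)
        for old, new in perm.items():
            labels2[mask.labels == old] = new
        mask2 = sn.LabelMask(labels2, 4)
        preds2 = {perm[k]: v for k, v in preds.items()}
        b = render_class_map(cube, mask2, preds2)
        np.testing.assert_array_equal(a.image, b.image)

    def test_painted_pixel_counts_match_roi_areas(self):
        cube, mask, classes = self._scene(n_seeds=6, seed=4)
        preds = {k: int(classes[k - 1]) for k in range(1, 7)}
        cm = render_class_map(cube, mask, preds)
        from seednet.viz import DEFAULT_PALETTE

        for cls in set(preds.values()):
            member_area = sum(
                (mask.labels == k).sum() for k, c in preds.items() if c == cls
            )
            color = np.array(DEFAULT_PALETTE[cls])
            painted = np.all(cm.image == color[None, None, :], axis=2).sum()
            assert painted == member_area

    def test_missing_prediction_names_seed(self):
        cube, mask, _ = self._scene(n_seeds=3, seed=5)
        with pytest.raises(ValueError, match="3"):
            render_class_map(cube, mask, {1: 0, 2: 1})


class TestRunComparison:
    def test_single_method_single_row(self, tiny_separable):
        data, split = tiny_separable
        table = run_comparison(data, split, ["LDA"])
        assert len(table) == 1
        assert table.iloc[0]["method"] == "LDA"
        assert 0 <= table.iloc[0]["test_accuracy"] <= 1

    def test_rerun_with_same_seed_is_identical(self, tiny_separable):
        data, split = tiny_separable
        kwargs = dict(seed=3, deep_cfg=sn.TrainConfig(epochs=2, batch_size=16, seed=3))
        a = run_comparison(data, split, ["LDA", "VGG"], **kwargs)
        b = run_comparison(data, split, ["LDA", "VGG"], **kwargs)
        assert a.equals(b)

    def test_unknown_method_rejected(self, tiny_separable):
        data, split = tiny_separable
        with pytest.raises(ValueError, match="unknown"):
            run_comparison(data, split, ["FOREST"])


@pytest.fixture(scope="module")
def source_model():
    cfg = sn.separable_config(n_classes=3, n_per_class=60, seed=0, n_bands=64)
    data = sn.generate_spectra(cfg)
    split = sn.split_stratified(data.labels, (3, 1, 1), seed=0)
    model = sn.build_vgg(data.n_bands, data.n_classes, seed=0)
    sn.train(model, data, split, sn.TrainConfig(epochs=8, batch_size=16, seed=0))
    return model


@pytest.fixture(scope="module")
def target():
    cfg = sn.SpectraGeneratorConfig(
        n_classes=3, n_per_class=250, seed=11, name="tgt",
        wavelengths=sn.default_wavelengths(64),
    )
    return sn.generate_spectra(cfg)


class TestRunSizeSweep:
    def test_full_fraction_matches_run_comparison(self, source_model, target):
        ft = sn.default_finetune_config(0)
        ft.epochs = 5
        report = run_size_sweep(
            source_model, [target], fractions=(1.0,), methods=("LDA",),
            seeds=(0,), finetune_cfg=ft,
        )
        split = sn.split_stratified(target.labels, (1, 2, 2), seed=0)
        table = run_comparison(target, split, ["LDA"])
        assert report.iloc[0]["test_accuracy"] == pytest.approx(
            table.iloc[0]["test_accuracy"]
        )

    def test_nested_training_subsets_and_ten_percent_rule(self, source_model, target):
        ft = sn.default_finetune_config(0)
        ft.epochs = 2
        report = run_size_sweep(
            source_model, [target], fractions=(0.1, 0.5, 1.0), methods=("LDA",),
            seeds=(0,), finetune_cfg=ft,
        )
        by_frac = report.set_index("fraction")["n_train"]
        assert by_frac[0.1] == 15  # 10% of 50 train/class, 3 classes -> 5 each
        assert by_frac[0.5] == 75
        assert by_frac[1.0] == 150
        # nesting: recompute splits and check containment
        full = sn.split_stratified(target.labels, (1, 2, 2), seed=0)
        s01 = sn.subsample_training(full, target.labels, 0.1, 0)
        s05 = sn.subsample_training(full, target.labels, 0.5, 0)
        assert set(s01.train_idx) < set(s05.train_idx)
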