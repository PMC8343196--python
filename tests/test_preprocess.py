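"""Wavelet denoising, stratified splits, subsampling, table I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import seednet as sn
from seednet.preprocess import crop_spectra


class TestWaveletDenoise:
    def test_constant_spectrum_unchanged(self):
        s = np.full(64, 0.7)
        out = sn.wavelet_denoise(s, sn.WaveletConfig())
        np.testing.assert_allclose(out, s, atol=1e-10)
        assert out.shape == s.shape

    def test_polynomial_preserved_by_hard_threshold(self):
        # db4 has 4 vanishing moments: a cubic has zero detail coefficients
        x = np.linspace(-1, 1, 64)
        s = 0.3 + 0.2 * x + 0.1 * x**2 - 0.05 * x**3
        cfg = sn.WaveletConfig(family="db4", level=2, threshold_rule="universal-hard",
                               mode="periodization")
        # periodization avoids boundary detail; interior must match closely
        out = sn.wavelet_denoise(s, cfg)
        np.testing.assert_allclose(out[8:-8], s[8:-8], atol=5e-3)

    def test_noise_reduction_on_smooth_spectrum(self):
        rng = np.random.default_rng(0)
        wl = np.linspace(975, 1646, 200)
        clean = 0.6 - 0.2 * np.exp(-0.5 * ((wl - 1300) / 40) ** 2)
        noisy = clean + rng.normal(0, 0.01, clean.size)
        out = sn.wavelet_denoise(noisy, sn.WaveletConfig())
        rmse_out = np.sqrt(np.mean((out - clean) ** 2))
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rmse_out < rmse_in

    def test_too_short_for_level_raises(self):
        with pytest.raises(ValueError, match="level"):
            sn.wavelet_denoise(np.ones(6), sn.WaveletConfig(level=3))


class TestSplitStratified:
    def test_pea_row_totals(self):
        labels = np.concatenate(
            [np.full(n, i) for i, n in enumerate([2697, 2848, 2849, 2026])]
        )
        split = sn.split_stratified(labels, (3, 1, 1), seed=4)
        assert split.counts() == (6252, 2084, 2084)

    @pytest.mark.parametrize(
        "n,ratio,expected",
        [
            (250, (1, 2, 2), (50, 100, 100)),
            (5, (3, 1, 1), (3, 1, 1)),
        ],
    )
    def test_exact_division(self, n, ratio, expected):
        labels = np.concatenate([np.full(n, 0), np.full(n, 1)])
        split = sn.split_stratified(labels, ratio, seed=0)
        per_class = tuple(
            int((labels[idx] == 0).sum())
            for idx in (split.train_idx, split.val_idx, split.test_idx)
        )
        assert per_class == expected

    @given(
        sizes=st.lists(st.integers(min_value=5, max_value=400), min_size=2, max_size=6),
        ratio=st.sampled_from([(3, 1, 1), (1, 2, 2), (2, 1, 1)]),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_counts_partition_each_class(self, sizes, ratio, seed):
        labels = np.concatenate([np.full(n, i) for i, n in enumerate(sizes)])
        split = sn.split_stratified(labels, ratio, seed)
        for cls, n in enumerate(sizes):
            parts = [int((labels[idx] == cls).sum())
                     for idx in (split.train_idx, split.val_idx, split.test_idx)]
            assert sum(parts) == n
            assert min(parts) >= 1
        union = np.concatenate([split.train_idx, split.val_idx, split.test_idx])
        assert np.array_equal(np.sort(union), np.arange(labels.size))

    def test_reproducible_and_seed_sensitive(self):
        labels = np.repeat(np.arange(3), 40)
        a = sn.split_stratified(labels, (3, 1, 1), seed=9)
        b = sn.split_stratified(labels, (3, 1, 1), seed=9)
        c = sn.split_stratified(labels, (3, 1, 1), seed=10)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert not np.array_equal(a.train_idx, c.train_idx)
        assert a.counts() == c.counts()

    def test_tiny_class_rejected(self):
        labels = np.concatenate([np.full(10, 0), np.full(2, 1)])
        with pytest.raises(ValueError, match="class 1"):
            sn.split_stratified(labels, (3, 1, 1), seed=0)

    def test_json_round_trip(self, tmp_path):
        labels = np.repeat(np.arange(2), 20)
        split = sn.split_stratified(labels, (3, 1, 1), seed=2)
        split.to_json(tmp_path / "s.json")
        back = sn.DataSplit.from_json(tmp_path / "s.json")
        assert np.array_equal(back.train_idx, split.train_idx)
        assert back.ratio == split.ratio and back.seed == split.seed


class TestSubsampleTraining:
    def _split(self, per_class=250, n_classes=4, seed=0):
        labels = np.repeat(np.arange(n_classes), per_class)
        return labels, sn.split_stratified(labels, (1, 2, 2), seed=seed)

    def test_ten_percent_of_fifty_is_five(self):
        labels, split = self._split()
        sub = sn.subsample_training(split, labels, 0.1, seed=0)
        assert np.all(np.bincount(labels[sub.train_idx]) == 5)
        assert np.array_equal(sub.val_idx, split.val_idx)
        assert np.array_equal(sub.test_idx, split.test_idx)

    def test_full_fraction_is_identity(self):
        labels, split = self._split()
        sub = sn.subsample_training(split, labels, 1.0, seed=0)
        assert np.array_equal(np.sort(sub.train_idx), np.sort(split.train_idx))

    def test_round_half_away(self):
        labels, split = self._split()
        sub = sn.subsample_training(split, labels, 0.34, seed=0)
        assert np.all(np.bincount(labels[sub.train_idx]) == 17)  # round(17.0)

    def test_nested_across_fractions(self):
        labels, split = self._split()
        subsets = {
            f: set(sn.subsample_training(split, labels, f, seed=3).train_idx)
            for f in (0.1, 0.2, 0.5, 1.0)
        }
        assert subsets[0.1] < subsets[0.2] < subsets[0.5] < subsets[1.0]

    def test_invalid_fraction(self):
        labels, split = self._split()
        with pytest.raises(ValueError):
            sn.subsample_training(split, labels, 0.0, seed=0)


class TestSpectraTable:
    def test_round_trip(self, tmp_path, small_grid):
        rng = np.random.default_rng(0)
        data = sn.LabeledSpectraSet(
            rng.uniform(0, 1, (10, 32)),
            rng.integers(0, 2, 10),
            ["alpha", "beta"],
            small_grid,
            name="toy",
        )
        sn.write_spectra_table(data, tmp_path / "t.csv")
        back = sn.read_spectra_table(tmp_path / "t.csv")
        np.testing.assert_allclose(back.spectra, data.spectra, atol=1e-9)
        assert np.array_equal(back.labels, data.labels)
        assert back.class_names == data.class_names

    def test_missing_label_column_raises(self, tmp_path):
        (tmp_path / "bad.csv").write_text("1000.0,1100.0\n0.5,0.6\n")
        with pytest.raises(ValueError, match="label"):
            sn.read_spectra_table(tmp_path / "bad.csv")

    def test_generated_table_class_counts(self, tmp_path):
        cfg = sn.SpectraGeneratorConfig(n_classes=3, n_per_class=100, seed=1,
                                        wavelengths=sn.default_wavelengths(40))
        sn.write_spectra_table(sn.generate_spectra(cfg), tmp_path / "g.csv")
        back = sn.read_spectra_table(tmp_path / "g.csv")
        assert np.all(back.class_counts() == 100)


def test_crop_spectra_matches_band_mask(small_grid):
    rng = np.random.default_rng(1)
    data = sn.LabeledSpectraSet(
        rng.uniform(0, 1, (6, 32)), rng.integers(0, 2, 6), ["a", "b"], small_grid
    )
    out = crop_spectra(data, 1100.0, 1500.0)
    keep = (small_grid.centers >= 1100.0) & (small_grid.centers <= 1500.0)
    np.testing.assert_array_equal(out.spectra, data.spectra[:, keep])
    assert len(out.wavelengths) == int(keep.sum())
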