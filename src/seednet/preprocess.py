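"""Spectra preprocessing and dataset bookkeeping.

Covers four stages between raw ROI spectra and model training:

* wavelet denoising of single spectra (universal threshold, MAD noise scale);
* the :class:`LabeledSpectraSet` container — an N x B spectra matrix with
  integer class ids, class names and the wavelength grid;
* stratified train/validation/test splitting at integer ratios (3:1:1 for a
  sample-rich source set, 1:2:2 for sample-limited targets), with a rounding
  rule that reproduces printed subset totals exactly;
* nested training-fraction subsampling for training-size sweeps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

from .types import WavelengthGrid

__all__ = [
    "LabeledSpectraSet",
    "DataSplit",
    "WaveletConfig",
    "wavelet_denoise",
    "split_stratified",
    "subsample_training",
    "crop_spectra",
    "read_spectra_table",
    "write_spectra_table",
]


@dataclass
class LabeledSpectraSet:
    """N labeled spectra on a common wavelength grid.

    Class ids are assigned in alphabetical order of ``class_names`` so that
    confusion matrices are comparable across runs.
    """

    spectra: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    wavelengths: WavelengthGrid
    name: str = ""

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.spectra.ndim != 2 or self.spectra.shape[0] == 0:
            raise ValueError("spectra must be a non-empty N x B matrix")
        if self.spectra.shape[0] != self.labels.shape[0]:
            raise ValueError("spectra and labels disagree on N")
        if self.spectra.shape[1] != len(self.wavelengths):
            raise ValueError("spectra band count does not match wavelength grid")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite entries")
        if self.labels.min() < 0 or self.labels.max() >= len(self.class_names):
            raise ValueError("labels outside 0..C-1")
        if list(self.class_names) != sorted(self.class_names):
            raise ValueError("class_names must be in alphabetical order")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


@dataclass
class DataSplit:
    """Disjoint train/validation/test indices into a LabeledSpectraSet."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    ratio: tuple[int, int, int]
    seed: int

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        union = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if union.size != np.unique(union).size:
            raise ValueError("split indices overlap")

    def counts(self) -> tuple[int, int, int]:
        return (len(self.train_idx), len(self.val_idx), len(self.test_idx))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "ratio": list(self.ratio),
                    "train": self.train_idx.tolist(),
                    "val": self.val_idx.tolist(),
                    "test": self.test_idx.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DataSplit":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["train"]), np.array(d["val"]), np.array(d["test"]),
            tuple(d["ratio"]), d["seed"],
        )


@dataclass
class WaveletConfig:
    """Wavelet shrinkage settings for spectrum denoising.

    ``db4`` at level 3 with a soft universal threshold is conventional for
    NIR reflectance spectra; all knobs are exposed because the right choice
    is instrument- and noise-dependent.
    """

    family: str = "db4"
    level: int = 3
    threshold_rule: str = "universal-soft"
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.family not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"{self.family!r} is not a discrete wavelet family")
        if self.threshold_rule not in ("universal-soft", "universal-hard"):
            raise ValueError("threshold_rule must be universal-soft or universal-hard")


def wavelet_denoise(spectrum: np.ndarray, cfg: WaveletConfig | None = None) -> np.ndarray:
    """Universal-threshold wavelet shrinkage of one spectrum.

    The noise scale sigma is estimated as MAD(finest detail)/0.6745 and all
    detail coefficients are thresholded at sigma * sqrt(2 ln n) (soft or
    hard), then the spectrum is reconstructed at original length.
    """
    cfg = cfg or WaveletConfig()
    s = np.asarray(spectrum, dtype=float)
    if s.ndim != 1:
        raise ValueError("spectrum must be 1-D")
    n = s.size
    if n < 2 ** cfg.level:
        raise ValueError(
            f"spectrum of length {n} too short for level {cfg.level}; "
            f"use level <= {int(np.log2(n))}"
        )
    coeffs = pywt.wavedec(s, cfg.family, level=cfg.level, mode=cfg.mode)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(n))
    mode = "soft" if cfg.threshold_rule == "universal-soft" else "hard"
    coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode=mode) for c in coeffs[1:]]
    return pywt.waverec(coeffs, cfg.family, mode=cfg.mode)[:n]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_stratified(
    labels: np.ndarray, ratio: tuple[int, int, int], seed: int
) -> DataSplit:
    """Per-class stratified split at integer ratio (a, b, c).

    For a class of size n: ``n_train = round(n*a/(a+b+c))``,
    ``n_val = round(n*b/(a+b+c))`` (round-half-away-from-zero) and the test
    set takes the exact remainder, so the three counts always sum to n.
    Membership comes from a seeded within-class shuffle; the assembled
    subsets are then shuffled across classes from the same seed stream.
    """
    labels = np.asarray(labels, dtype=int)
    a, b, c = ratio
    if min(a, b, c) <= 0:
        raise ValueError("ratio parts must be positive")
    total = a + b + c
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    train, val, test = [], [], []
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        n = idx.size
        if n < 3:
            raise ValueError(f"class {cls} has {n} < 3 members")
        n_train = _round_half_away(n * a / total)
        n_val = _round_half_away(n * b / total)
        n_test = n - n_train - n_val
        if min(n_train, n_val, n_test) <= 0:
            raise ValueError(
                f"class {cls} (size {n}) yields an empty subset at ratio {ratio}"
            )
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        val.append(perm[n_train:n_train + n_val])
        test.append(perm[n_train + n_val:])
    train_idx = rng.permutation(np.concatenate(train))
    val_idx = rng.permutation(np.concatenate(val))
    test_idx = rng.permutation(np.concatenate(test))
    return DataSplit(train_idx, val_idx, test_idx, (a, b, c), seed)


def subsample_training(
    split: DataSplit, labels: np.ndarray, fraction: float, seed: int
) -> DataSplit:
    """Keep a per-class fraction of the training indices; val/test untouched.

    Per class, ``max(1, round(fraction * n_train_class))`` indices are kept
    as the prefix of one seeded per-class permutation, so for a fixed seed
    the 10% subset of each class is contained in its 20% subset and the
    size sweep is monotone in information.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    labels = np.asarray(labels, dtype=int)
    kept = []
    for cls in np.unique(labels[split.train_idx]):
        cls_train = split.train_idx[labels[split.train_idx] == cls]
        rng = np.random.default_rng([seed, int(cls)])
        perm = rng.permutation(cls_train)
        n_keep = max(1, _round_half_away(fraction * cls_train.size))
        kept.append(perm[:n_keep])
    train_idx = np.sort(np.concatenate(kept))
    return DataSplit(train_idx, split.val_idx, split.test_idx, split.ratio, seed)


def crop_spectra(dataset: LabeledSpectraSet, lo_nm: float, hi_nm: float) -> LabeledSpectraSet:
    """Restrict a spectra set to bands in the closed interval [lo_nm, hi_nm]."""
    centers = dataset.wavelengths.centers
    keep = (centers >= lo_nm) & (centers <= hi_nm)
    if not np.any(keep):
        raise ValueError(f"no bands in range [{lo_nm}, {hi_nm}] nm")
    return LabeledSpectraSet(
        dataset.spectra[:, keep],
        dataset.labels,
        list(dataset.class_names),
        WavelengthGrid(centers[keep]),
        name=dataset.name,
    )


# ---------------------------------------------------------------------------
# spectra table I/O: header "label,<wl_1>,...,<wl_B>", one class name per row


def write_spectra_table(dataset: LabeledSpectraSet, path: str | Path, sep: str = ",") -> Path:
    path = Path(path)
    df = pd.DataFrame(dataset.spectra,
                      columns=[f"{w:.6f}" for w in dataset.wavelengths.centers])
    df.insert(0, "label", [dataset.class_names[i] for i in dataset.labels])
    df.to_csv(path, sep=sep, index=False)
    return path


def read_spectra_table(path: str | Path, sep: str = ",", name: str = "") -> LabeledSpectraSet:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed spectra table {path}: {exc}") from exc
    if "label" not in df.columns:
        raise ValueError(f"spectra table {path} lacks a 'label' column")
    names = sorted(df["label"].astype(str).unique())
    name_to_id = {n: i for i, n in enumerate(names)}
    labels = df["label"].astype(str).map(name_to_id).to_numpy()
    wl_cols = [c for c in df.columns if c != "label"]
    try:
        wavelengths = WavelengthGrid(np.array([float(c) for c in wl_cols]))
    except ValueError as exc:
        raise ValueError(f"bad wavelength header in {path}: {exc}") from exc
    spectra = df[wl_cols].to_numpy(dtype=float)
    return LabeledSpectraSet(spectra, labels, names, wavelengths,
                             name=name or path.stem)
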