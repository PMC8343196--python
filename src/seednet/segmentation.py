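"""Seed localisation and per-seed spectrum extraction.

Each seed on the conveyor scene is one region of interest (ROI).  The band
with the strongest seed/background contrast is thresholded (Otsu), cleaned by
morphological opening, and connected components become seeds.  Every pixel
spectrum of an ROI is passed through an optional per-pixel transform (the
wavelet denoiser in the standard pipeline) *before* averaging — the mean of
transformed spectra, not the transform of the mean, is the sample unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk, opening

from .types import SpectralCube

__all__ = [
    "SeedROI",
    "LabelMask",
    "select_contrast_band",
    "segment_seeds",
    "extract_roi_spectra",
]

logger = logging.getLogger(__name__)


@dataclass
class SeedROI:
    """One seed: its pixels, bounding box, centroid and mean spectrum."""

    label_id: int
    pixel_mask: np.ndarray  # (n_pixels, 2) array of (row, col)
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max) inclusive
    centroid: tuple[float, float]
    mean_spectrum: np.ndarray

    @property
    def area(self) -> int:
        return int(self.pixel_mask.shape[0])


@dataclass
class LabelMask:
    """H x W integer raster: 0 = background, k in 1..n_seeds = seed k."""

    labels: np.ndarray
    n_seeds: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        expected = np.arange(self.n_seeds + 1)
        if self.n_seeds and not np.array_equal(present[present > 0],
                                               expected[expected > 0]):
            raise ValueError("labels must be exactly {0} u {1..n_seeds}")


def select_contrast_band(cube: SpectralCube) -> int:
    """Index of the band with the strongest seed/background contrast.

    Contrast is scored as Otsu inter-class variance of the band image, which
    is maximal when foreground and background form two well-separated modes.
    Deterministic; a constant cube has no contrast and raises.
    """
    best_idx, best_score = -1, -np.inf
    for bi in range(cube.shape[2]):
        img = cube.data[:, :, bi]
        if np.ptp(img) == 0:
            continue
        t = threshold_otsu(img)
        fg = img > t
        w1 = fg.mean()
        w0 = 1.0 - w1
        if w0 == 0 or w1 == 0:
            continue
        score = w0 * w1 * (img[fg].mean() - img[~fg].mean()) ** 2
        if score > best_score:
            best_idx, best_score = bi, score
    if best_idx < 0:
        raise ValueError("no contrast: every band image is constant")
    return best_idx


def segment_seeds(
    band_image: np.ndarray,
    min_area: int = 20,
    opening_radius: int = 1,
    closing_radius: int = 0,
) -> LabelMask:
    """Threshold + morphology + connected components on one band image.

    Otsu threshold -> binary mask -> opening (disk ``opening_radius``;
    optional closing) -> 8-connected labeling -> components below
    ``min_area`` dropped -> labels renumbered 1..n in raster-scan order of
    each component's first pixel.
    """
    img = np.asarray(band_image, dtype=float)
    if img.ndim != 2 or not np.all(np.isfinite(img)):
        raise ValueError("band image must be a finite 2-D array")
    if np.ptp(img) == 0:
        logger.info("segment_seeds: constant image, no seeds")
        return LabelMask(np.zeros(img.shape, dtype=np.int32), 0)
    binary = img > threshold_otsu(img)
    if opening_radius > 0:
        binary = opening(binary, disk(opening_radius)).astype(bool)
    if closing_radius > 0:
        binary = closing(binary, disk(closing_radius)).astype(bool)
    raw_labels = cc_label(binary, connectivity=2)  # 8-connectivity
    out = np.zeros(img.shape, dtype=np.int32)
    next_id = 0
    # raster-scan order of first pixel = order of first appearance in C order
    seen: dict[int, int] = {}
    flat = raw_labels.ravel()
    counts = np.bincount(flat)
    for lab in flat:
        if lab == 0 or lab in seen:
            continue
        if counts[lab] < min_area:
            seen[lab] = 0
            continue
        next_id += 1
        seen[lab] = next_id
    for lab, new in seen.items():
        if new:
            out[raw_labels == lab] = new
    if next_id == 0:
        logger.info("segment_seeds: no components of area >= %d", min_area)
    return LabelMask(out, next_id)


def extract_roi_spectra(
    cube: SpectralCube,
    mask: LabelMask,
    per_pixel_transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[SeedROI]:
    """Per-seed mean spectra, transforming every pixel spectrum first.

    ``per_pixel_transform`` maps a B-vector to a B-vector (e.g. the wavelet
    denoiser); ``None`` is the identity.  ROIs are returned in label order.
    """
    if cube.shape[:2] != mask.labels.shape:
        raise ValueError(
            f"cube H x W {cube.shape[:2]} does not match mask {mask.labels.shape}"
        )
    rois: list[SeedROI] = []
    for k in range(1, mask.n_seeds + 1):
        rows, cols = np.nonzero(mask.labels == k)
        spectra = cube.data[rows, cols, :].astype(float)
        if per_pixel_transform is not None:
            spectra = np.stack([per_pixel_transform(s) for s in spectra])
        rois.append(
            SeedROI(
                label_id=k,
                pixel_mask=np.column_stack([rows, cols]),
                bbox=(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())),
                centroid=(float(rows.mean()), float(cols.mean())),
                mean_spectrum=spectra.mean(axis=0),
            )
        )
    return rois


def roi_table(rois: Sequence[SeedROI]) -> "np.ndarray":
    """Structured summary (label_id, bbox, centroid, area) for export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label_id": [r.label_id for r in rois],
            "row_min": [r.bbox[0] for r in rois],
            "col_min": [r.bbox[1] for r in rois],
            "row_max": [r.bbox[2] for r in rois],
            "col_max": [r.bbox[3] for r in rois],
            "centroid_row": [r.centroid[0] for r in rois],
            "centroid_col": [r.centroid[1] for r in rois],
            "area": [r.area for r in rois],
        }
    )
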