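"""t-SNE feature-space views and spatial classification maps.

Two diagnostics for a trained network: 2-D t-SNE embeddings of the raw
spectra and of the activations at the flatten/Fc1/Fc2 feature points
(class structure should tighten with depth), and a classification map that
paints every segmented seed with its predicted class color on top of a
grayscale band image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

from .deep_models import extract_features
from .nn import Network
from .preprocess import LabeledSpectraSet
from .segmentation import LabelMask
from .types import SpectralCube

__all__ = ["EmbeddingResult", "ClassMap", "tsne_layers", "render_class_map", "DEFAULT_PALETTE"]

# tab10-style colors, one per class id
DEFAULT_PALETTE = (
    (0.12, 0.47, 0.71), (1.00, 0.50, 0.05), (0.17, 0.63, 0.17),
    (0.84, 0.15, 0.16), (0.58, 0.40, 0.74), (0.55, 0.34, 0.29),
    (0.89, 0.47, 0.76), (0.50, 0.50, 0.50), (0.74, 0.74, 0.13),
    (0.09, 0.75, 0.81),
)


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # N x 2
    layer_name: str
    perplexity: float
    seed: int
    sample_labels: np.ndarray


@dataclass
class ClassMap:
    image: np.ndarray  # H x W x 3 in [0, 1]
    legend: dict  # class id -> color


def tsne_layers(
    model: Network | None,
    data: LabeledSpectraSet,
    idx: np.ndarray,
    layers: list[str] = ("raw", "flatten", "Fc1", "Fc2"),
    perplexity: float = 30.0,
    seed: int = 0,
) -> list[EmbeddingResult]:
    """One seeded 2-D embedding per requested feature point.

    ``raw`` embeds the input spectra directly (``model`` may be None then).
    """
    idx = np.asarray(idx, dtype=int)
    if idx.size < 3 * perplexity:
        raise ValueError(
            f"{idx.size} samples < 3 x perplexity ({perplexity}); lower the perplexity"
        )
    results = []
    for layer in layers:
        if layer == "raw":
            feats = data.spectra[idx]
        else:
            if model is None:
                raise ValueError("a model is required for non-raw layers")
            feats = extract_features(model, layer, data, idx)
        coords = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
            max_iter=1000,
            # the exact solver keeps coincident inputs coincident; fall back
            # to Barnes-Hut only where the quadratic cost would bite
            method="exact" if idx.size <= 500 else "barnes_hut",
        ).fit_transform(np.asarray(feats, dtype=np.float64))
        results.append(
            EmbeddingResult(coords, layer, perplexity, seed, data.labels[idx].copy())
        )
    return results


def render_class_map(
    cube: SpectralCube,
    mask: LabelMask,
    predictions: dict[int, int] | np.ndarray,
    palette: tuple = DEFAULT_PALETTE,
    band_index: int | None = None,
) -> ClassMap:
    """Paint each seed's pixels with its predicted class color.

    ``predictions`` maps seed label_id -> class id (an array is read as
    predictions for seeds 1..n in order).  Background keeps the grayscale
    band image.
    """
    if isinstance(predictions, np.ndarray) or isinstance(predictions, list):
        predictions = {k + 1: int(c) for k, c in enumerate(predictions)}
    missing = [k for k in range(1, mask.n_seeds + 1) if k not in predictions]
    if missing:
        raise ValueError(f"missing prediction for seed label_id(s) {missing}")
    if band_index is None:
        band_index = cube.shape[2] // 2
    base = cube.data[:, :, band_index].astype(float)
    span = np.ptp(base)
    gray = (base - base.min()) / span if span > 0 else np.zeros_like(base)
    image = np.repeat(gray[:, :, None], 3, axis=2)
    legend = {}
    for k in range(1, mask.n_seeds + 1):
        color = palette[predictions[k] % len(palette)]
        image[mask.labels == k] = color
        legend[predictions[k]] = color
    return ClassMap(image, legend)
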