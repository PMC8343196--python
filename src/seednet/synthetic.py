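"""Seeded generators for synthetic seed spectra and hyperspectral scenes.

Real NIR reflectance spectra of crop seeds share a smooth baseline with
absorption features from common constituents — carbohydrate C-H overtones
near 1119 and 1207 nm, amide/protein bands near 1308 and 1470 nm — while
varieties differ in feature depth, offset and tilt.  The generator emulates
exactly that structure: a smooth baseline minus class-modulated Gaussian
absorptions, plus class offset/slope, smooth correlated noise and white
noise.  A domain-pair generator reuses a controllable fraction of the
source's absorption dictionary to build "different but related" target
crops (or, at zero sharing, an unrelated domain for negative-transfer
stress tests).  A scene generator renders non-overlapping elliptical seeds
into raw/white/dark reference cubes so the full calibration-to-
classification pipeline can be exercised end to end against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .preprocess import LabeledSpectraSet
from .segmentation import LabelMask
from .types import CalibrationTriplet, SpectralCube, WavelengthGrid

__all__ = [
    "SpectraGeneratorConfig",
    "SceneGeneratorConfig",
    "generate_spectra",
    "generate_domain_pair",
    "generate_scene",
    "class_mean_profile",
    "default_wavelengths",
    "sensor_wavelengths",
    "separable_config",
]

DEFAULT_PEAKS = (1119.45, 1206.92, 1307.97, 1469.95)


def default_wavelengths(n_bands: int = 200) -> WavelengthGrid:
    """The usable NIR window, 975-1646 nm, uniformly sampled."""
    return WavelengthGrid(np.linspace(975.0, 1646.0, n_bands))


def sensor_wavelengths(n_bands: int = 256) -> WavelengthGrid:
    """The full sensor range, 874.41-1733.91 nm (head/tail are noisy)."""
    return WavelengthGrid(np.linspace(874.41, 1733.91, n_bands))


@dataclass
class SpectraGeneratorConfig:
    """Statistical description of one crop's labeled spectra.

    ``class_effects`` is a (C, K+2) matrix: per-peak amplitude deltas, then
    a reflectance offset and a slope term per class.  ``None`` draws a
    fixed pattern from the seed, scaled by ``effect_scale`` so separability
    grows monotonically with that dial.
    """

    n_classes: int = 4
    n_per_class: int = 2600
    wavelengths: WavelengthGrid = field(default_factory=default_wavelengths)
    peak_centers: Sequence[float] = DEFAULT_PEAKS
    peak_widths: float | Sequence[float] = 25.0
    base_amplitude: float = 0.12
    effect_scale: float = 1.0
    class_effects: np.ndarray | None = None
    within_class_sd: float = 0.005
    correlated_noise_scale: float = 0.01
    # per-sample baseline drift (offset, slope, curvature sd): the additive
    # scatter nuisance of NIR reflectance, deliberately left uncorrected
    drift_sd: tuple[float, float, float] = (0.03, 0.02, 0.015)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_per_class < 3:
            raise ValueError("n_per_class must be >= 3")
        lo, hi = self.wavelengths.centers[0], self.wavelengths.centers[-1]
        for c in self.peak_centers:
            if not lo <= c <= hi:
                raise ValueError(f"peak center {c} nm outside grid [{lo}, {hi}]")

    def resolved_effects(self) -> np.ndarray:
        k = len(self.peak_centers)
        if self.class_effects is not None:
            eff = np.asarray(self.class_effects, dtype=float)
            if eff.shape != (self.n_classes, k + 2):
                raise ValueError(f"class_effects must be ({self.n_classes}, {k + 2})")
            return eff
        rng = np.random.default_rng([self.seed, 1017])
        pattern = np.empty((self.n_classes, k + 2))
        # class signal lives mainly in absorption depths; offsets/slopes are
        # small because per-sample drift would mask them anyway
        pattern[:, :k] = rng.uniform(-0.5, 0.5, (self.n_classes, k)) * self.base_amplitude
        pattern[:, k] = rng.uniform(-0.01, 0.01, self.n_classes)
        pattern[:, k + 1] = rng.uniform(-0.008, 0.008, self.n_classes)
        return self.effect_scale * pattern

    def class_names(self) -> list[str]:
        return [f"{self.name}_var{i:02d}" for i in range(self.n_classes)]


def separable_config(
    n_classes: int = 4, n_per_class: int = 600, seed: int = 0, n_bands: int = 200
) -> SpectraGeneratorConfig:
    """A zero-overlap benchmark: strong class effects, mild noise."""
    return SpectraGeneratorConfig(
        n_classes=n_classes,
        n_per_class=n_per_class,
        wavelengths=default_wavelengths(n_bands),
        effect_scale=2.0,
        within_class_sd=0.004,
        correlated_noise_scale=0.004,
        drift_sd=(0.005, 0.004, 0.003),
        seed=seed,
        name="separable",
    )


def _baseline(wl: np.ndarray) -> np.ndarray:
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.55 + 0.08 * np.sin(2.2 * u + 0.4) - 0.05 * u


def class_mean_profile(cfg: SpectraGeneratorConfig, class_id: int) -> np.ndarray:
    """The noiseless mean spectrum of one class under ``cfg``."""
    wl = cfg.wavelengths.centers
    k = len(cfg.peak_centers)
    widths = np.broadcast_to(np.atleast_1d(cfg.peak_widths), (k,))
    eff = cfg.resolved_effects()[class_id]
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    profile = _baseline(wl) + eff[k] + eff[k + 1] * (u - 0.5)
    for j, (center, width) in enumerate(zip(cfg.peak_centers, widths)):
        amp = max(cfg.base_amplitude + eff[j], 0.0)
        profile = profile - amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return profile


def _sample_noise(rng: np.random.Generator, n: int, b: int,
                  corr_scale: float, white_sd: float,
                  drift_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    noise = np.zeros((n, b))
    u = np.linspace(-0.5, 0.5, b)
    off_sd, slope_sd, curve_sd = drift_sd
    if off_sd > 0:
        noise += rng.normal(0, off_sd, (n, 1))
    if slope_sd > 0:
        noise += rng.normal(0, slope_sd, (n, 1)) * u[None, :]
    if curve_sd > 0:
        noise += rng.normal(0, curve_sd, (n, 1)) * (4 * u**2 - 1 / 3)[None, :]
    if corr_scale > 0:
        noise += corr_scale * gaussian_filter1d(
            rng.standard_normal((n, b)), sigma=8.0, axis=1
        )
    if white_sd > 0:
        noise += white_sd * rng.standard_normal((n, b))
    return noise


def generate_spectra(cfg: SpectraGeneratorConfig) -> LabeledSpectraSet:
    """Draw a balanced labeled spectra set; bit-reproducible under seed."""
    rng = np.random.default_rng(cfg.seed)
    b = len(cfg.wavelengths)
    blocks, labels = [], []
    for cls in range(cfg.n_classes):
        profile = class_mean_profile(cfg, cls)
        noise = _sample_noise(rng, cfg.n_per_class, b,
                              cfg.correlated_noise_scale, cfg.within_class_sd,
                              cfg.drift_sd)
        blocks.append(profile[None, :] + noise)
        labels.append(np.full(cfg.n_per_class, cls))
    return LabeledSpectraSet(
        np.concatenate(blocks),
        np.concatenate(labels),
        cfg.class_names(),
        cfg.wavelengths,
        name=cfg.name,
    )


def generate_domain_pair(
    source_cfg: SpectraGeneratorConfig,
    target_cfg: SpectraGeneratorConfig,
    shared_structure: float = 0.8,
) -> tuple[LabeledSpectraSet, LabeledSpectraSet]:
    """A source set plus a domain-shifted target set.

    The target reuses ``round(shared_structure * K)`` of the source's K
    absorption centers and draws the rest afresh; its class effects come
    from its own seed.  ``shared_structure = 0`` yields an unrelated
    feature dictionary (negative-transfer stress test).
    """
    if not 0 <= shared_structure <= 1:
        raise ValueError("shared_structure must be in [0, 1]")
    k = len(source_cfg.peak_centers)
    n_shared = int(round(shared_structure * k))
    rng = np.random.default_rng([target_cfg.seed, 4099])
    lo = target_cfg.wavelengths.centers[0] + 30.0
    hi = target_cfg.wavelengths.centers[-1] - 30.0
    centers = list(source_cfg.peak_centers[:n_shared])
    for _ in range(k - n_shared):
        for _attempt in range(200):
            c = float(rng.uniform(lo, hi))
            if all(abs(c - o) >= 40.0 for o in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError("could not place a fresh absorption center")
    shifted = replace(target_cfg, peak_centers=tuple(centers))
    return generate_spectra(source_cfg), generate_spectra(shifted)


@dataclass
class SceneGeneratorConfig:
    """A conveyor-belt scene: elliptical seeds on a dark plate."""

    image_size: tuple[int, int] = (96, 128)
    n_seeds: int = 20
    axes_range: tuple[float, float] = (5.0, 9.0)
    background_level: float = 0.08
    spectra_config: SpectraGeneratorConfig = field(
        default_factory=lambda: SpectraGeneratorConfig(
            wavelengths=sensor_wavelengths(), n_per_class=3
        )
    )
    white_level: float = 4000.0
    dark_level: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if 2 * self.axes_range[1] + 4 > min(self.image_size):
            raise ValueError("seeds do not fit inside the image")


def generate_scene(
    cfg: SceneGeneratorConfig,
) -> tuple[CalibrationTriplet, LabelMask, np.ndarray, list[str]]:
    """Render a scene and its ground truth.

    Returns the raw/white/dark calibration triplet (so ``calibrate``
    recovers the intended reflectances exactly), the ground-truth label
    mask (raster-scan numbering), the per-seed class ids and class names.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    scfg = cfg.spectra_config
    b = len(scfg.wavelengths)
    margin = cfg.axes_range[1] + 2
    placed: list[tuple[float, float, float, float, float]] = []
    for _seed_i in range(cfg.n_seeds):
        for _attempt in range(2000):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ay = rng.uniform(*cfg.axes_range)
            ax = rng.uniform(*cfg.axes_range)
            theta = rng.uniform(0, np.pi)
            if all(
                np.hypot(cy - oy, cx - ox) > (max(ay, ax) + max(oay, oax) + 3)
                for oy, ox, oay, oax, _ in placed
            ):
                placed.append((cy, cx, ay, ax, theta))
                break
        else:
            raise RuntimeError(
                f"could not place {cfg.n_seeds} non-overlapping seeds; "
                "use a larger image or fewer seeds"
            )
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.int32)
    for k, (cy, cx, ay, ax, theta) in enumerate(placed, start=1):
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        mask[(u / ay) ** 2 + (v / ax) ** 2 <= 1.0] = k
    # renumber in raster-scan order of first pixel
    order = []
    for lab in mask.ravel():
        if lab and lab not in order:
            order.append(lab)
    remap = {old: new for new, old in enumerate(order, start=1)}
    mask = np.vectorize(lambda v: remap.get(v, 0))(mask).astype(np.int32)
    n_seeds = len(order)

    seed_classes = rng.integers(0, scfg.n_classes, size=n_seeds)
    reflect = np.full((h, w, b), cfg.background_level, dtype=float)
    for k in range(1, n_seeds + 1):
        rows, cols = np.nonzero(mask == k)
        profile = class_mean_profile(scfg, int(seed_classes[k - 1]))
        noise = _sample_noise(rng, rows.size, b,
                              scfg.correlated_noise_scale, scfg.within_class_sd,
                              scfg.drift_sd)
        reflect[rows, cols, :] = np.clip(profile[None, :] + noise, 0.0, None)

    wlg = scfg.wavelengths
    white = np.full((h, w, b), cfg.white_level)
    dark = np.full((h, w, b), cfg.dark_level)
    raw = dark + reflect * (white - dark)
    triplet = CalibrationTriplet(
        raw=SpectralCube(raw, wlg, kind="raw"),
        white=SpectralCube(white, wlg, kind="white_ref"),
        dark=SpectralCube(dark, wlg, kind="dark_ref"),
    )
    return triplet, LabelMask(mask, n_seeds), seed_classes, scfg.class_names()
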