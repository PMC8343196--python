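"""From a raw hyperspectral scene to per-seed mean spectra.

Renders a synthetic conveyor scene (20 elliptical seeds, 256-band cubes with
white/dark references), then runs the standard pipeline: reflectance
calibration, cropping to the usable 975-1646 nm window, contrast-band
selection, Otsu segmentation, and per-seed spectrum extraction with
per-pixel wavelet denoising.
"""

import seednet as sn

triplet, truth, seed_classes, class_names = sn.generate_scene(
    sn.SceneGeneratorConfig(seed=5)
)
print(f"scene: raw cube {triplet.raw.shape}, {truth.n_seeds} seeds placed")

cube = sn.crop_bands(sn.calibrate(triplet), 975.0, 1646.0)
print(f"calibrated reflectance cube cropped to {cube.shape[2]} bands")

band = sn.select_contrast_band(cube)
mask = sn.segment_seeds(cube.data[:, :, band], min_area=20, opening_radius=1)
print(f"contrast band index {band}; segmentation found {mask.n_seeds} seeds")

denoise = lambda s: sn.wavelet_denoise(s, sn.WaveletConfig())
rois = sn.extract_roi_spectra(cube, mask, per_pixel_transform=denoise)
r = rois[0]
print(f"seed 1: area {r.area} px, bbox {r.bbox}, "
      f"mean reflectance {r.mean_spectrum.mean():.3f}")
# Each ROI's mean spectrum (pixels denoised before averaging) is the sample
# unit that the classifiers consume.
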