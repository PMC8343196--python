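"""Core domain containers for hyperspectral seed imaging.

A hyperspectral scan is an H x W x B raster (B contiguous NIR bands) with a
band-center wavelength grid.  Raw sensor counts are converted to relative
reflectance with white/dark reference scans; every seed found in the scene is
reduced to one mean reflectance spectrum, the sample unit for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "SpectralCube",
    "CalibrationTriplet",
    "CubeKind",
]

CubeKind = ("raw", "white_ref", "dark_ref", "reflectance")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-center wavelengths in nanometres."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("wavelength grid needs at least 2 band centers")
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise ValueError("wavelength centers must be finite and positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("wavelength centers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.centers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.centers.shape == other.centers.shape and bool(
            np.allclose(self.centers, other.centers)
        )


@dataclass
class SpectralCube:
    """H x W x B raster of radiance counts or relative reflectance.

    ``kind`` tracks the radiometric state; reflectance may exceed 1 (specular
    highlights) but must stay finite.
    """

    data: np.ndarray
    wavelengths: WavelengthGrid
    kind: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be H x W x B, got shape {self.data.shape}")
        if self.data.shape[2] != len(self.wavelengths):
            raise ValueError(
                f"band axis ({self.data.shape[2]}) does not match wavelength "
                f"grid ({len(self.wavelengths)})"
            )
        if self.kind not in CubeKind:
            raise ValueError(f"kind must be one of {CubeKind}, got {self.kind!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class CalibrationTriplet:
    """Raw scan plus white (high-reflectance) and dark (shutter) references."""

    raw: SpectralCube
    white: SpectralCube
    dark: SpectralCube

    def __post_init__(self) -> None:
        expected = {"raw": "raw", "white": "white_ref", "dark": "dark_ref"}
        for name, kind in expected.items():
            cube = getattr(self, name)
            if cube.kind != kind:
                raise ValueError(f"{name} cube has kind {cube.kind!r}, expected {kind!r}")
        if not (self.raw.shape == self.white.shape == self.dark.shape):
            raise ValueError("calibration cubes must share one shape")
        if not (self.raw.wavelengths == self.white.wavelengths == self.dark.wavelengths):
            raise ValueError("calibration cubes must share one wavelength grid")
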