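"""Hyperspectral cube I/O, reflectance calibration and band cropping.

Three dialects are supported:

``envi``
    The de-facto HSI interchange format: an ASCII ``.hdr`` describing a flat
    binary raster (``samples``/``lines``/``bands``, ``interleave`` in
    {bil, bip, bsq}, ``data type``, ``wavelength = {...}``).
``hdf5``
    One HDF5 dataset ``cube`` with a ``wavelengths`` array and ``kind``
    attribute.
``delimited-bands``
    A plain-text stack: one header line per band (``# band <wl>``) followed by
    the H x W values — convenient for tiny fixtures and debugging.

Calibration follows the standard two-point radiometric correction
``R = (I_raw - I_dark) / (I_white - I_dark)`` applied per pixel and band.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np

from .types import CalibrationTriplet, SpectralCube, WavelengthGrid

__all__ = ["read_cube", "write_cube", "calibrate", "crop_bands", "FormatError"]

logger = logging.getLogger(__name__)

# ENVI data type codes <-> numpy dtypes (the subset we emit)
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class FormatError(ValueError):
    """Malformed or inconsistent cube file."""


# ---------------------------------------------------------------------------
# ENVI dialect


def _parse_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_braces:
            buf.append(line)
            if line.endswith("}"):
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip().lower(), value.strip()
        if value.startswith("{") and not value.endswith("}"):
            buf = [value]
            in_braces = True
        else:
            fields[key] = value
    return fields


def _read_envi(path: Path) -> SpectralCube:
    hdr = path.with_suffix(".hdr") if path.suffix != ".hdr" else path
    if not hdr.exists():
        raise FormatError(f"missing ENVI header {hdr}")
    fields = _parse_envi_header(hdr)
    for req in ("samples", "lines", "bands", "interleave", "data type", "wavelength"):
        if req not in fields:
            raise FormatError(f"ENVI header missing field {req!r}")
    w = int(fields["samples"])
    h = int(fields["lines"])
    b = int(fields["bands"])
    interleave = fields["interleave"].lower()
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(t) for t in wl_text.replace(",", " ").split()])
    if wavelengths.size != b:
        raise FormatError(
            f"header declares bands={b} but wavelength lists {wavelengths.size} values"
        )
    raw_path = hdr.with_suffix(".raw")
    if not raw_path.exists():
        raise FormatError(f"missing ENVI binary {raw_path}")
    flat = np.fromfile(raw_path, dtype=_ENVI_DTYPES[code])
    if flat.size != h * w * b:
        raise FormatError(
            f"binary holds {flat.size} values, header implies {h * w * b}"
        )
    if interleave == "bsq":  # (bands, lines, samples)
        data = flat.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        data = flat.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bip":  # (lines, samples, bands)
        data = flat.reshape(h, w, b)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")
    kind = fields.get("kind", "raw").strip()
    return SpectralCube(data.astype(np.float64, copy=True) if code in (4, 5) else data,
                        WavelengthGrid(wavelengths), kind=kind)


def _write_envi(cube: SpectralCube, path: Path) -> None:
    hdr = path.with_suffix(".hdr")
    raw = path.with_suffix(".raw")
    data = np.asarray(cube.data)
    dtype = data.dtype if data.dtype in _DTYPE_CODES else np.dtype(np.float64)
    h, w, b = data.shape
    wl = ", ".join(f"{c:.6f}" for c in cube.wavelengths.centers)
    hdr.write_text(
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "interleave = bil\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"kind = {cube.kind}\n"
        "wavelength = {" + wl + "}\n"
    )
    data.astype(dtype).transpose(0, 2, 1).tofile(raw)  # BIL: line, band, sample


# ---------------------------------------------------------------------------
# HDF5 dialect


def _read_hdf5(path: Path) -> SpectralCube:
    with h5py.File(path, "r") as f:
        if "cube" not in f:
            raise FormatError("HDF5 file lacks a 'cube' dataset")
        data = f["cube"][()]
        if "wavelengths" not in f:
            raise FormatError("HDF5 file lacks a 'wavelengths' dataset")
        wl = f["wavelengths"][()]
        kind = f["cube"].attrs.get("kind", "raw")
        if isinstance(kind, bytes):
            kind = kind.decode()
    if data.ndim != 3 or data.shape[2] != wl.size:
        raise FormatError(
            f"cube shape {data.shape} inconsistent with {wl.size} wavelengths"
        )
    return SpectralCube(data, WavelengthGrid(wl), kind=str(kind))


def _write_hdf5(cube: SpectralCube, path: Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("cube", data=cube.data)
        d.attrs["kind"] = cube.kind
        f.create_dataset("wavelengths", data=cube.wavelengths.centers)


# ---------------------------------------------------------------------------
# delimited text dialect


def _read_delimited(path: Path) -> SpectralCube:
    planes, wavelengths = [], []
    current: list[list[float]] = []
    kind = "raw"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# kind"):
            kind = line.split()[-1]
        elif line.startswith("# band"):
            if current:
                planes.append(current)
            wavelengths.append(float(line.split()[-1]))
            current = []
        else:
            current.append([float(t) for t in line.replace(",", " ").split()])
    if current:
        planes.append(current)
    if not planes:
        raise FormatError("delimited cube file contains no band sections")
    if len(planes) != len(wavelengths):
        raise FormatError("band sections and wavelength headers disagree")
    widths = {len(row) for plane in planes for row in plane}
    heights = {len(plane) for plane in planes}
    if len(widths) != 1 or len(heights) != 1:
        raise FormatError("ragged rows: all band planes must share H x W")
    data = np.array(planes).transpose(1, 2, 0)
    return SpectralCube(data, WavelengthGrid(np.array(wavelengths)), kind=kind)


def _write_delimited(cube: SpectralCube, path: Path) -> None:
    lines = [f"# kind {cube.kind}"]
    for bi, wl in enumerate(cube.wavelengths.centers):
        lines.append(f"# band {wl:.6f}")
        for row in cube.data[:, :, bi]:
            lines.append(" ".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


_DIALECTS = {
    "envi": (_read_envi, _write_envi),
    "hdf5": (_read_hdf5, _write_hdf5),
    "delimited-bands": (_read_delimited, _write_delimited),
}


def read_cube(path: str | Path, dialect: str = "envi") -> SpectralCube:
    """Read a hyperspectral cube; see module docstring for dialects."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    path = Path(path)
    if not path.exists() and not (dialect == "envi" and path.with_suffix(".hdr").exists()):
        raise FileNotFoundError(path)
    return _DIALECTS[dialect][0](path)


def write_cube(cube: SpectralCube, path: str | Path, dialect: str = "envi") -> Path:
    """Write ``cube`` so that :func:`read_cube` round-trips it."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _DIALECTS[dialect][1](cube, path)
    return path


# ---------------------------------------------------------------------------
# calibration and band cropping


def calibrate(triplet: CalibrationTriplet) -> SpectralCube:
    """Two-point radiometric correction ``(raw - dark) / (white - dark)``.

    Pixels where white and dark references coincide (dead detector elements)
    are set to 0 and counted in a logged warning instead of raising.
    """
    num = triplet.raw.data.astype(np.float64) - triplet.dark.data.astype(np.float64)
    den = triplet.white.data.astype(np.float64) - triplet.dark.data.astype(np.float64)
    dead = den == 0
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~dead)
    if np.any(dead):
        logger.warning(
            "calibrate: %d voxel(s) with white == dark set to 0", int(dead.sum())
        )
    return SpectralCube(
        out,
        triplet.raw.wavelengths,
        kind="reflectance",
        metadata=dict(triplet.raw.metadata),
    )


def crop_bands(cube: SpectralCube, lo_nm: float, hi_nm: float) -> SpectralCube:
    """Keep bands with centers in the closed interval [lo_nm, hi_nm].

    The head and tail of the sensor range carry instrument noise; the usable
    window for NIR seed spectra here is conventionally 975-1646 nm.
    """
    if lo_nm >= hi_nm:
        raise ValueError(f"lo_nm ({lo_nm}) must be < hi_nm ({hi_nm})")
    centers = cube.wavelengths.centers
    keep = (centers >= lo_nm) & (centers <= hi_nm)
    if not np.any(keep):
        raise ValueError(f"no bands in range [{lo_nm}, {hi_nm}] nm")
    return SpectralCube(
        cube.data[:, :, keep],
        WavelengthGrid(centers[keep]),
        kind=cube.kind,
        metadata=dict(cube.metadata),
    )
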