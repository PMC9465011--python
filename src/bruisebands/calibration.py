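"""Flat-field reflectance calibration and ENVI raster I/O.

Raw digital numbers are converted to relative reflectance with the usual
white/dark reference correction

    I_R = (I_r - I_d) / (I_w - I_d),

which cancels the wavelength-dependent system throughput (lamp spectrum,
optics, detector response) and the fixed dark offset.  Entries where the
white signal does not exceed the dark signal carry no radiometric
information and are flagged invalid instead of being clipped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .synthetic_data import HyperCube, SpectralAxis

__all__ = ["ReflectanceCube", "flat_field", "read_envi", "write_envi"]


@dataclass(frozen=True)
class ReflectanceCube:
    """Relative reflectance raster with a per-entry validity mask."""

    data: np.ndarray        # (lines, samples, bands) float
    axis: SpectralAxis
    valid_mask: np.ndarray  # bool, same shape as data

    def __post_init__(self) -> None:
        if self.data.shape != self.valid_mask.shape:
            raise ValueError("valid_mask shape must match data shape")
        if self.data.shape[2] != self.axis.n_bands:
            raise ValueError("band count does not match the spectral axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band(self, nm: float) -> np.ndarray:
        return self.data[:, :, self.axis.index_of(nm, tol_nm=np.inf)]


def flat_field(raw: HyperCube, white: HyperCube, dark: HyperCube) -> ReflectanceCube:
    """Flat-field correction of a raw cube against white/dark references.

    References may be full cubes or single frames (``lines == 1``) that
    broadcast along the scan axis.  Entries where ``white <= dark`` are
    flagged invalid (value NaN), never silently clipped.
    """
    if not (raw.axis == white.axis and raw.axis == dark.axis):
        raise ValueError("raw/white/dark spectral axes differ")
    for ref, name in ((white, "white"), (dark, "dark")):
        if ref.shape[1:] != raw.shape[1:]:
            raise ValueError(f"{name} frame samples/bands do not match raw cube")
        if ref.shape[0] not in (1, raw.shape[0]):
            raise ValueError(f"{name} frame lines must be 1 or match raw cube")

    w = np.asarray(white.data, dtype=float)
    d = np.asarray(dark.data, dtype=float)
    r = np.asarray(raw.data, dtype=float)
    denom = w - d
    valid = np.broadcast_to(denom > 0, r.shape).copy()
    if not valid.any():
        raise ValueError("white reference nowhere exceeds dark reference")
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (r - d) / denom
    refl = np.where(valid, refl, np.nan)
    return ReflectanceCube(refl, raw.axis, valid)


# --------------------------------------------------------------------------
# ENVI raster I/O
# --------------------------------------------------------------------------
# Minimal ENVI support: BIL/BSQ/BIP interleaves, little-endian uint16 or
# float32/float64 pixels, ASCII .hdr with a mandatory wavelength list.

_DTYPES = {2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, _, rest = line.partition("=")
            key = key.strip().lower()
            buf = rest.strip()
        else:
            buf += " " + line
        if buf.count("{") > buf.count("}"):
            continue
        fields[key] = buf.strip()
        key = None
    return fields


def read_envi(path: str) -> HyperCube:
    """Read an ENVI raster (``path`` is the binary file; header ``path.hdr``).

    The header must carry ``samples``, ``lines``, ``bands``, ``data type``,
    ``interleave`` and a ``wavelength`` list; anything else is an error.
    """
    hdr_path = path + ".hdr"
    if not os.path.exists(hdr_path):
        raise FileNotFoundError(hdr_path)
    fields = _parse_header(open(hdr_path).read())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")
    if dtype_code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    wl = np.array(
        [float(tok) for tok in fields["wavelength"].strip("{} ").split(",") if tok.strip()]
    )
    if wl.size != bands:
        raise ValueError("wavelength list length does not match band count")
    kind = fields.get("cube kind", "raw").strip()

    flat = np.fromfile(path, dtype=_DTYPES[dtype_code])
    if flat.size != lines * samples * bands:
        raise ValueError("raster size does not match header dimensions")
    if interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return HyperCube(np.ascontiguousarray(data), SpectralAxis(wl), kind)


def write_envi(cube: HyperCube, path: str, interleave: str = "bil") -> None:
    """Write a cube as an ENVI raster + ASCII header (``path`` and ``path.hdr``)."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    data = np.asarray(cube.data)
    if data.dtype not in _DTYPE_CODES:
        data = data.astype(
            np.uint16 if np.issubdtype(data.dtype, np.integer) else np.float64
        )
    lines, samples, bands = data.shape
    if interleave == "bil":
        out = data.transpose(0, 2, 1)
    elif interleave == "bsq":
        out = data.transpose(2, 0, 1)
    else:
        out = data
    np.ascontiguousarray(out).tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in cube.axis.wavelengths_nm)
    with open(path + ".hdr", "w") as fh:
        fh.write(
            "ENVI\n"
            f"samples = {samples}\n"
            f"lines = {lines}\n"
            f"bands = {bands}\n"
            "header offset = 0\n"
            "file type = ENVI Standard\n"
            f"data type = {_DTYPE_CODES[data.dtype]}\n"
            f"interleave = {interleave}\n"
            "byte order = 0\n"
            f"cube kind = {cube.kind}\n"
            f"wavelength = {{ {wl} }}\n"
        )
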