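"""Hyperspectral cube data model and file I/O.

A cube is a rows x cols x bands array of raw camera counts or unitless
reflectance, together with its wavelength grid.  The instrument emulated
here records 121 contiguous bands from 400 to 1000 nm at 5 nm steps.

On disk the canonical dialect is ENVI (a plain-text ``.hdr`` next to a raw
binary payload); band-stacked TIFF with a sidecar wavelength header is also
supported.  Spatial indexing is 0-based, row-major, origin at top-left, and
region-of-interest masks share this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "WavelengthGrid",
    "Hypercube",
    "RoiMask",
    "read_cube",
    "write_cube",
    "calibrate_reflectance",
    "extract_roi_spectrum",
    "read_mask",
    "write_mask",
    "read_fit_table",
    "write_fit_table",
]

#: Default band centres in nm: 400, 405, ..., 1000 (121 bands).
DEFAULT_WAVELENGTHS = np.arange(400.0, 1000.0 + 2.5, 5.0)

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64,
                12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-centre wavelengths in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("wavelength grid must be a 1-D array of values")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        return cls(DEFAULT_WAVELENGTHS.copy())

    @property
    def spacing(self) -> float:
        """Mean band spacing in nm (uniform for the default grid)."""
        if len(self.values) < 2:
            raise ValueError("spacing undefined for a single-band grid")
        return float(np.mean(np.diff(self.values)))

    def is_uniform(self, tol: float = 1e-9) -> bool:
        d = np.diff(self.values)
        return bool(np.all(np.abs(d - d[0]) <= tol))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, rtol=0, atol=1e-9)
        )


@dataclass
class Hypercube:
    """rows x cols x bands grid of counts or reflectance."""

    data: np.ndarray
    wavelengths: WavelengthGrid
    kind: str = "raw"  # {"raw", "reflectance"}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != len(self.wavelengths):
            raise ValueError(
                f"bands axis ({self.data.shape[2]}) does not match wavelength "
                f"count ({len(self.wavelengths)})"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def spatial_shape(self) -> tuple:
        return self.data.shape[:2]


@dataclass
class RoiMask:
    """Binary region-of-interest mask aligned with a cube's spatial axes."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D binary grid")
        if not self.pixels.any():
            raise ValueError("mask must contain at least one true pixel")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def size(self) -> int:
        return int(self.pixels.sum())


# ---------------------------------------------------------------------------
# ENVI dialect

def _write_envi(cube: Hypercube, path: Path, interleave: str = "bsq") -> None:
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    data = np.ascontiguousarray(cube.data)
    rows, cols, bands = data.shape
    code = _ENVI_CODES.get(data.dtype)
    if code is None:
        data = data.astype(np.float64)
        code = _ENVI_CODES[data.dtype]
    if interleave == "bsq":
        payload = np.transpose(data, (2, 0, 1))
    elif interleave == "bil":
        payload = np.transpose(data, (0, 2, 1))
    else:  # bip: rows, cols, bands
        payload = data
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths.values)
    meta_lines = "".join(
        f"{k} = {v}\n" for k, v in sorted(cube.meta.items()) if k not in ("kind",)
    )
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"kind = {cube.kind}\n"
        f"{meta_lines}"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)
    payload.astype(payload.dtype.newbyteorder("<")).tofile(path)


def _parse_envi_header(text: str) -> dict:
    # ENVI headers are "key = value" lines; {...} blocks may span lines.
    out: dict = {}
    body = text.replace("\r\n", "\n")
    i = 0
    lines = body.split("\n")
    while i < len(lines):
        line = lines[i]
        i += 1
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            parts = [val]
            while i < len(lines) and "}" not in lines[i]:
                parts.append(lines[i])
                i += 1
            if i < len(lines):
                parts.append(lines[i])
                i += 1
            val = " ".join(parts)
        out[key] = val
    return out


def _read_envi(path: Path) -> Hypercube:
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"no ENVI header for {path}")
    hdr = _parse_envi_header(hdr_path.read_text())
    rows = int(hdr["lines"])
    cols = int(hdr["samples"])
    bands = int(hdr["bands"])
    dtype = _ENVI_DTYPES[int(hdr["data type"])]
    interleave = hdr.get("interleave", "bsq").lower()
    raw = np.fromfile(path, dtype=np.dtype(dtype).newbyteorder("<"))
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"payload size {raw.size} inconsistent with header "
            f"{rows}x{cols}x{bands}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    if "wavelength" in hdr:
        wl_str = hdr["wavelength"].strip().strip("{}")
        wl = np.array([float(x) for x in wl_str.replace(",", " ").split()])
        if wl.size != bands:
            raise ValueError(
                f"header lists {wl.size} wavelengths but {bands} bands"
            )
        grid = WavelengthGrid(wl)
    else:
        if bands != len(DEFAULT_WAVELENGTHS):
            raise ValueError(
                f"no wavelengths in header and band count {bands} does not "
                f"match the default 121-band grid"
            )
        grid = WavelengthGrid.default()
    kind = hdr.get("kind", "raw")
    reserved = {"samples", "lines", "bands", "header offset", "file type",
                "data type", "interleave", "byte order", "kind",
                "wavelength", "wavelength units", "description"}
    meta = {k: v for k, v in hdr.items() if k not in reserved}
    return Hypercube(np.ascontiguousarray(data), grid, kind=kind, meta=meta)


# ---------------------------------------------------------------------------
# TIFF stack dialect (multi-page TIFF + sidecar text header)

def _write_tiff(cube: Hypercube, path: Path) -> None:
    import tifffile

    pages = np.transpose(np.ascontiguousarray(cube.data), (2, 0, 1))
    tifffile.imwrite(path, pages)
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths.values)
    side = (
        f"kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
        + "".join(f"{k} = {v}\n" for k, v in sorted(cube.meta.items()))
    )
    Path(str(path) + ".hdr").write_text(side)


def _read_tiff(path: Path) -> Hypercube:
    import tifffile

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.transpose(pages, (1, 2, 0))
    side_path = Path(str(path) + ".hdr")
    kind, meta = "raw", {}
    if side_path.exists():
        hdr = _parse_envi_header(side_path.read_text())
        kind = hdr.get("kind", "raw")
        if "wavelength" in hdr:
            wl_str = hdr["wavelength"].strip().strip("{}")
            wl = np.array([float(x) for x in wl_str.replace(",", " ").split()])
            if wl.size != data.shape[2]:
                raise ValueError(
                    f"sidecar lists {wl.size} wavelengths but cube has "
                    f"{data.shape[2]} bands"
                )
            grid = WavelengthGrid(wl)
        else:
            grid = WavelengthGrid.default()
        meta = {k: v for k, v in hdr.items() if k not in ("kind", "wavelength")}
    else:
        if data.shape[2] != len(DEFAULT_WAVELENGTHS):
            raise ValueError(
                "no sidecar header and band count does not match default grid"
            )
        grid = WavelengthGrid.default()
    return Hypercube(np.ascontiguousarray(data), grid, kind=kind, meta=meta)


def read_cube(path, format: str = "envi") -> Hypercube:
    """Read a hypercube from disk.

    Parameters
    ----------
    path
        Binary payload path (ENVI) or TIFF path.
    format
        ``"envi"`` or ``"tiff_stack"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "envi":
        return _read_envi(path)
    if format == "tiff_stack":
        return _read_tiff(path)
    raise ValueError(f"unknown cube format {format!r}")


def write_cube(cube: Hypercube, path, format: str = "envi",
               interleave: str = "bsq") -> None:
    """Write a hypercube losslessly for its numeric dtype."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "envi":
        _write_envi(cube, path, interleave=interleave)
    elif format == "tiff_stack":
        _write_tiff(cube, path)
    else:
        raise ValueError(f"unknown cube format {format!r}")


# ---------------------------------------------------------------------------
# Reflectance calibration

def calibrate_reflectance(raw: Hypercube, white: Hypercube,
                          dark: Hypercube | None = None,
                          clip_max: float = 2.0) -> Hypercube:
    """Convert raw counts to reflectance: R = (I - D) / (W - D).

    The dark frame is optional and defaults to all zeros, in which case the
    formula degenerates to the plain white-reference ratio I / W.  Output is
    clipped to [0, clip_max]; the number of clipped values is recorded in
    ``meta["clip_count"]``.
    """
    for other, name in ((white, "white"), (dark, "dark")):
        if other is None:
            continue
        if other.data.shape != raw.data.shape:
            raise ValueError(f"{name} frame shape {other.data.shape} does not "
                             f"match raw shape {raw.data.shape}")
        if other.wavelengths != raw.wavelengths:
            raise ValueError(f"{name} frame wavelength grid differs from raw")
    d = dark.data.astype(float) if dark is not None else 0.0
    denom = white.data.astype(float) - d
    bad = denom <= 0
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"white - dark <= 0 at (row, col, band) = {idx}; cannot calibrate"
        )
    refl = (raw.data.astype(float) - d) / denom
    clip_count = int(np.sum((refl < 0) | (refl > clip_max)))
    refl = np.clip(refl, 0.0, clip_max)
    meta = dict(raw.meta)
    meta["clip_count"] = str(clip_count)
    return Hypercube(refl, raw.wavelengths, kind="reflectance", meta=meta)


def extract_roi_spectrum(cube: Hypercube, mask: RoiMask,
                         reducer: str = "mean") -> np.ndarray:
    """Per-band reduction of a reflectance cube over the masked pixels."""
    if cube.kind != "reflectance":
        raise ValueError("ROI spectra are extracted from reflectance cubes")
    if mask.shape != cube.spatial_shape():
        raise ValueError(
            f"mask shape {mask.shape} does not match cube spatial shape "
            f"{cube.spatial_shape()}"
        )
    px = cube.data[mask.pixels]  # (n_pixels, bands)
    if reducer == "mean":
        return px.mean(axis=0)
    if reducer == "median":
        return np.median(px, axis=0)
    raise ValueError(f"unknown reducer {reducer!r}")


# ---------------------------------------------------------------------------
# Mask and FIT-table I/O

def write_mask(mask: RoiMask, path) -> None:
    """Write a mask as an 8-bit single-channel PNG (0 outside, 255 inside)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def read_mask(path) -> RoiMask:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., 0]
    return RoiMask(img > 127)


def read_fit_table(path):
    """Read the per-area FIT table (case_id, area_id, fit_ng_per_ml)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"case_id", "area_id", "fit_ng_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FIT table missing columns: {sorted(missing)}")
    return df


def write_fit_table(df, path) -> None:
    import pandas as pd  # noqa: F401

    df.to_csv(path, index=False)
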