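"""Hyperspectral cube I/O, reflectance calibration and matrix conversion.

A hyperspectral image is held as a :class:`SpectralCube`: a ``rows x cols x
bands`` array together with the band-center wavelengths in nanometres.
Cubes are read and written as ENVI-style pairs (a raw binary payload plus an
ASCII header declaring ``samples``, ``lines``, ``bands``, ``interleave``,
``data type`` and a ``wavelength`` list).  Supported interleaves are
``bsq``/``bil``/``bip`` and data types float32 / uint16; wavelengths are
assumed to be nanometres unless the header states otherwise.

Raw sensor counts are converted to reflectance against a white reference
standard and a closed-shutter dark-current measurement,

    R = (raw - dark) / (white - dark),

per pixel and band.  For clustering, a cube is flattened into a dense
``m x n`` signature matrix (wavelength rows, one column per unmasked pixel)
with a back-map from columns to pixel coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CalibrationError,
    ConsistencyError,
    CorruptFileError,
    FormatError,
    ParameterError,
)

__all__ = [
    "SpectralCube",
    "CalibrationSet",
    "SpectralMatrix",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_reflectance",
    "cube_to_matrix",
    "matrix_to_map",
]

_ENVI_DTYPES = {4: np.float32, 12: np.uint16}
_ENVI_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}
_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class SpectralCube:
    """A spatially resolved spectrum grid: ``values[row, col, band]``.

    ``wavelengths`` holds the band centers in nm, strictly increasing, one
    per band.  ``meta`` carries provenance (source path, calibration state,
    image id) and is never interpreted by the numerics.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ParameterError(
                f"cube values must be 3D (rows x cols x bands), got {self.values.ndim}D"
            )
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ParameterError(
                f"wavelength list length {len(self.wavelengths)} does not match "
                f"band count {self.values.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ParameterError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def validate_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("cube contains non-finite values (NaN/Inf)")


@dataclass
class CalibrationSet:
    """White-reference and dark-current measurements for one acquisition.

    Each member is either a full :class:`SpectralCube` (spatially resolved
    reference) or a per-band vector; both are common in practice and the
    calibration broadcasts accordingly.
    """

    white: SpectralCube | np.ndarray
    dark: SpectralCube | np.ndarray

    def _as_array(self, ref) -> np.ndarray:
        if isinstance(ref, SpectralCube):
            return ref.values
        return np.asarray(ref, dtype=float)

    def white_array(self) -> np.ndarray:
        return self._as_array(self.white)

    def dark_array(self) -> np.ndarray:
        return self._as_array(self.dark)


@dataclass
class SpectralMatrix:
    """Dense signature matrix ``X`` (m wavelengths x n pixels).

    Column ``j`` is the spectrum of pixel ``pixel_index[j] = (image_id,
    row, col)``; the back-map is a bijection onto the unmasked pixels of the
    source image(s), in row-major scan order per image.
    """

    X: np.ndarray
    pixel_index: list[tuple[str | int, int, int]]
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ParameterError("X must be 2D (wavelengths x signatures)")
        if self.X.shape[0] != len(self.wavelengths):
            raise ParameterError("row count of X must equal number of wavelengths")
        if self.X.shape[1] != len(self.pixel_index):
            raise ConsistencyError("pixel_index length must equal column count of X")

    @property
    def n_signatures(self) -> int:
        return self.X.shape[1]

    @property
    def n_bands(self) -> int:
        return self.X.shape[0]

    @property
    def image_ids(self) -> list:
        """Distinct image ids, in first-appearance order."""
        seen: dict = {}
        for img, _, _ in self.pixel_index:
            seen.setdefault(img, None)
        return list(seen)


# ---------------------------------------------------------------------------
# ENVI dialect codec
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([A-Za-z][A-Za-z0-9 _]*?)\s*=\s*(\{[^}]*\}|[^\n]*)",
                         re.M | re.S)
    for m in pattern.finditer(text):
        key = " ".join(m.group(1).lower().split())
        fields[key] = m.group(2).strip()
    return fields


def _parse_brace_list(value: str) -> list[str]:
    inner = value.strip()
    if inner.startswith("{"):
        inner = inner[1:]
    if inner.endswith("}"):
        inner = inner[:-1]
    return [tok.strip() for tok in inner.split(",") if tok.strip()]


def read_envi_cube(image_path, header_path=None) -> SpectralCube:
    """Read an ENVI image/header pair into a :class:`SpectralCube`.

    ``header_path`` defaults to ``image_path`` with a ``.hdr`` suffix.  The
    cube is returned in rows x cols x bands order regardless of the on-disk
    interleave.
    """
    image_path = Path(image_path)
    if header_path is None:
        header_path = image_path.with_suffix(".hdr")
    header_path = Path(header_path)

    fields = _parse_envi_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc

    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no wavelength list")

    wavelengths = np.array([float(w) for w in _parse_brace_list(fields["wavelength"])])
    if len(wavelengths) != bands:
        raise CorruptFileError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )

    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))
    payload = np.fromfile(image_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if payload.size != expected:
        raise CorruptFileError(
            f"payload holds {payload.size} values, header implies {expected}"
        )

    if interleave == "bsq":
        values = payload.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = payload.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        values = payload.reshape(lines, samples, bands)

    meta = {"source": str(image_path), "interleave": interleave}
    return SpectralCube(np.ascontiguousarray(values), wavelengths, meta)


def write_envi_cube(cube: SpectralCube, image_path, header_path=None,
                    interleave: str = "bsq", dtype=np.float32) -> None:
    """Write a cube as an ENVI pair; lossless for the chosen numeric type."""
    image_path = Path(image_path)
    if header_path is None:
        header_path = image_path.with_suffix(".hdr")
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ParameterError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _ENVI_DTYPE_CODES:
        raise ParameterError(f"unsupported dtype {dtype}; use float32 or uint16")
    cube.validate_finite()

    rows, cols, bands = cube.shape
    values = cube.values.astype(dtype)
    if interleave == "bsq":
        payload = values.transpose(2, 0, 1)
    elif interleave == "bil":
        payload = values.transpose(0, 2, 1)
    else:  # bip
        payload = values

    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {xhclust export}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(payload).tofile(image_path)


# ---------------------------------------------------------------------------
# Reflectance calibration
# ---------------------------------------------------------------------------

def calibrate_reflectance(raw: SpectralCube, cal: CalibrationSet) -> SpectralCube:
    """Normalize raw counts to reflectance, R = (raw - dark)/(white - dark).

    References may be full cubes (per-pixel normalisation) or per-band
    vectors.  Reflectance above 1 (overexposure) is preserved here and
    handled later by masking.  Raises :class:`CalibrationError` naming the
    first band where white - dark is not strictly positive.
    """
    raw_v = raw.values.astype(float)
    white = cal.white_array().astype(float)
    dark = cal.dark_array().astype(float)
    for name, ref in (("white", white), ("dark", dark)):
        if ref.ndim == 1:
            if len(ref) != raw.n_bands:
                raise CalibrationError(
                    f"{name} reference has {len(ref)} bands, cube has {raw.n_bands}"
                )
        elif ref.shape != raw_v.shape:
            raise CalibrationError(
                f"{name} reference shape {ref.shape} does not match cube {raw_v.shape}"
            )

    denom = white - dark
    bad = ~(denom > 0)
    if np.any(bad):
        per_band = np.any(bad, axis=tuple(range(bad.ndim - 1))) if bad.ndim > 1 else bad
        raise CalibrationError(
            f"white - dark not strictly positive in band(s) "
            f"{np.flatnonzero(per_band).tolist()}"
        )

    reflectance = (raw_v - dark) / denom
    meta = dict(raw.meta)
    meta["calibrated"] = True
    return SpectralCube(reflectance, raw.wavelengths.copy(), meta)


# ---------------------------------------------------------------------------
# Cube <-> matrix conversion
# ---------------------------------------------------------------------------

def cube_to_matrix(cube: SpectralCube, mask=None) -> SpectralMatrix:
    """Flatten unmasked pixels into an ``m x n`` signature matrix.

    Columns follow a row-major scan of unmasked pixels, so the layout is
    deterministic.  ``mask`` is a :class:`~xhclust.preprocess.PixelMask`
    (or a boolean exclusion grid); ``None`` keeps every pixel.
    """
    rows, cols, _ = cube.shape
    if mask is None:
        excluded = np.zeros((rows, cols), dtype=bool)
    else:
        excluded = np.asarray(getattr(mask, "excluded", mask), dtype=bool)
        if excluded.shape != (rows, cols):
            raise ConsistencyError(
                f"mask shape {excluded.shape} does not match cube spatial "
                f"shape {(rows, cols)}"
            )
    keep = ~excluded
    n = int(keep.sum())
    if n == 0:
        raise ParameterError("all pixels are masked; signature matrix would be empty")

    image_id = cube.meta.get("image_id", 0)
    rr, cc = np.nonzero(keep)  # row-major order
    X = cube.values[rr, cc, :].T.astype(float)
    pixel_index = [(image_id, int(r), int(c)) for r, c in zip(rr, cc)]
    return SpectralMatrix(X, pixel_index, cube.wavelengths.copy())


def matrix_to_map(labels, pixel_index, spatial_shape, k=None, image_id=None):
    """Scatter per-column labels back onto the pixel grid.

    Returns a :class:`~xhclust.cluster.ClusterMap` whose grid holds labels
    ``1..k`` at unmasked pixels and 0 (unlabelled) elsewhere.
    """
    from .cluster import ClusterMap  # local import to avoid a module cycle

    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(pixel_index):
        raise ConsistencyError("labels length must equal pixel_index length")
    rows, cols = spatial_shape
    grid = np.zeros((rows, cols), dtype=np.int32)
    seen = np.zeros((rows, cols), dtype=bool)
    for lab, (img, r, c) in zip(labels, pixel_index):
        if not (0 <= r < rows and 0 <= c < cols):
            raise ConsistencyError(f"pixel index ({r}, {c}) outside grid {spatial_shape}")
        if seen[r, c]:
            raise ConsistencyError(f"duplicate pixel index entry ({r}, {c})")
        seen[r, c] = True
        grid[r, c] = lab
        if image_id is None:
            image_id = img
    if k is None:
        k = int(grid.max()) if grid.size else 0
    return ClusterMap(labels=grid, k=int(k), image_id=image_id)
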