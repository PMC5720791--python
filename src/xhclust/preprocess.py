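"""Spectral preprocessing: smoothing, band cropping, pixel masking.

Reflectance spectra from visible/NIR push-broom cameras are noisy at the
extremes of the sensor range, so the standard chain is: Savitzky-Golay
smoothing of every pixel spectrum (degree-5 polynomial, 7 supporting points
on each side by default), cropping to the reliable 450-790 nm window, and
masking of pixels that carry no tissue signal — the dark dish background and
fluid-covered patches whose reflectance exceeds 1 through specular
overexposure.  The fixed pipeline order is calibrate -> smooth -> crop ->
mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ParameterError
from .hsi_io import SpectralCube, SpectralMatrix

__all__ = [
    "PixelMask",
    "SmoothingParams",
    "REASON_NONE",
    "REASON_BACKGROUND",
    "REASON_OVEREXPOSED",
    "REASON_USER",
    "savgol_smooth",
    "smooth_cube",
    "crop_bands",
    "build_mask",
    "circular_roi_mask",
]

REASON_NONE = 0
REASON_BACKGROUND = 1
REASON_OVEREXPOSED = 2
REASON_USER = 3

_REASON_NAMES = {
    REASON_NONE: "none",
    REASON_BACKGROUND: "background",
    REASON_OVEREXPOSED: "overexposed",
    REASON_USER: "user",
}


@dataclass
class PixelMask:
    """Per-pixel exclusion grid with a reason code for every excluded pixel.

    ``excluded[r, c]`` is True for pixels left out of the analysis;
    ``reason`` holds one of the ``REASON_*`` codes.  Masks compose
    monotonically: the union of two masks never unmasks a pixel.
    """

    excluded: np.ndarray
    reason: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.reason is None:
            self.reason = np.where(self.excluded, REASON_USER, REASON_NONE).astype(np.uint8)
        else:
            self.reason = np.asarray(self.reason, dtype=np.uint8)
        if self.reason.shape != self.excluded.shape:
            raise ParameterError("reason grid must match excluded grid shape")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.excluded.shape

    def count(self, reason_code: int | None = None) -> int:
        if reason_code is None:
            return int(self.excluded.sum())
        return int(np.sum(self.excluded & (self.reason == reason_code)))

    def union(self, other: "PixelMask") -> "PixelMask":
        """Combine two masks; existing reasons win where both exclude."""
        if other.spatial_shape != self.spatial_shape:
            raise ParameterError("cannot union masks of different shapes")
        excluded = self.excluded | other.excluded
        reason = np.where(self.excluded, self.reason, other.reason).astype(np.uint8)
        return PixelMask(excluded, reason)

    def __or__(self, other: "PixelMask") -> "PixelMask":
        return self.union(other)


@dataclass
class SmoothingParams:
    """Savitzky-Golay settings: ``polyorder`` and points per side.

    The window length is ``2 * half_window + 1`` and must exceed
    ``polyorder``.  Defaults follow a degree-5 fit on 7 points to the left
    and right of each band.
    """

    polyorder: int = 5
    half_window: int = 7

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ParameterError("half_window must be >= 1")
        if self.window_length <= self.polyorder:
            raise ParameterError(
                f"window length {self.window_length} must exceed polyorder {self.polyorder}"
            )

    @property
    def window_length(self) -> int:
        return 2 * self.half_window + 1


def _edge_weights(offsets: np.ndarray, polyorder: int) -> np.ndarray:
    # Least-squares degree-p fit on the truncated window, evaluated at
    # offset 0; pinv reproduces polynomials up to the fit order exactly.
    V = np.vander(offsets.astype(float), polyorder + 1, increasing=True)
    return np.linalg.pinv(V)[0]


def _savgol_columns(arr: np.ndarray, params: SmoothingParams) -> np.ndarray:
    m = arr.shape[0]
    w = params.window_length
    if m < w:
        raise ParameterError(
            f"spectrum has {m} bands, fewer than the window length {w}"
        )
    out = savgol_filter(arr, w, params.polyorder, axis=0, mode="interp")
    hw = params.half_window
    # Near the ends the window is shrunk to the available points (same
    # polynomial order) instead of extrapolating beyond the measured range.
    for p in range(hw):
        idx = np.arange(0, p + hw + 1)
        out[p] = _edge_weights(idx - p, params.polyorder) @ arr[idx]
        q = m - 1 - p
        idx2 = np.arange(q - hw, m)
        out[q] = _edge_weights(idx2 - q, params.polyorder) @ arr[idx2]
    return out


def savgol_smooth(matrix: SpectralMatrix, params: SmoothingParams | None = None) -> SpectralMatrix:
    """Smooth every signature along the wavelength axis.

    Each column is filtered independently; interior bands match the
    classical Savitzky-Golay convolution, end bands use a shrunk fit window
    of the same polynomial order.
    """
    params = params or SmoothingParams()
    smoothed = _savgol_columns(matrix.X, params)
    return SpectralMatrix(smoothed, list(matrix.pixel_index), matrix.wavelengths.copy())


def smooth_cube(cube: SpectralCube, params: SmoothingParams | None = None) -> SpectralCube:
    """Cube-level smoothing: every pixel spectrum filtered independently."""
    params = params or SmoothingParams()
    rows, cols, bands = cube.shape
    flat = cube.values.reshape(rows * cols, bands).T
    smoothed = _savgol_columns(flat, params)
    meta = dict(cube.meta)
    meta["smoothed"] = {"polyorder": params.polyorder, "half_window": params.half_window}
    return SpectralCube(smoothed.T.reshape(rows, cols, bands), cube.wavelengths.copy(), meta)


def crop_bands(data, lo_nm: float = 450.0, hi_nm: float = 790.0):
    """Retain only bands with ``lo_nm <= wavelength <= hi_nm`` (closed).

    Works on a :class:`SpectralCube` or a :class:`SpectralMatrix`; the
    wavelength list is cropped consistently.  Idempotent.
    """
    if lo_nm >= hi_nm:
        raise ParameterError(f"lo_nm ({lo_nm}) must be below hi_nm ({hi_nm})")
    wl = np.asarray(data.wavelengths)
    keep = (wl >= lo_nm) & (wl <= hi_nm)
    if not np.any(keep):
        raise ParameterError(f"no bands inside [{lo_nm}, {hi_nm}] nm")
    if isinstance(data, SpectralCube):
        meta = dict(data.meta)
        meta["crop_nm"] = (lo_nm, hi_nm)
        return SpectralCube(data.values[:, :, keep], wl[keep], meta)
    if isinstance(data, SpectralMatrix):
        return SpectralMatrix(data.X[keep, :], list(data.pixel_index), wl[keep])
    raise ParameterError(f"cannot crop object of type {type(data).__name__}")


def build_mask(cube: SpectralCube, background_rule=0.05,
               overexposure_threshold: float = 1.0) -> PixelMask:
    """Flag background and overexposed pixels of a reflectance cube.

    A pixel is overexposed iff its maximum reflectance over the retained
    bands strictly exceeds ``overexposure_threshold`` (specular fluid
    patches).  ``background_rule`` is either a mean-reflectance threshold
    (pixels darker than it are background — defensible for a low-reflectance
    dish) or a callable ``cube -> bool grid``.
    """
    values = cube.values
    over = values.max(axis=2) > overexposure_threshold
    if callable(background_rule):
        background = np.asarray(background_rule(cube), dtype=bool)
        if background.shape != cube.spatial_shape:
            raise ParameterError("background rule returned a grid of the wrong shape")
    else:
        background = values.mean(axis=2) < float(background_rule)
    background = background & ~over

    excluded = over | background
    reason = np.zeros(cube.spatial_shape, dtype=np.uint8)
    reason[background] = REASON_BACKGROUND
    reason[over] = REASON_OVEREXPOSED
    return PixelMask(excluded, reason)


def circular_roi_mask(spatial_shape, center, diameter_px: float) -> PixelMask:
    """Exclude everything outside a circular region of interest.

    Pixels whose Euclidean distance from ``center`` (row, col) exceeds
    ``diameter_px / 2`` are excluded with the user reason code.  Used to
    restrict quantification to the wound disc (e.g. a 5 mm-diameter area).
    """
    if diameter_px <= 0:
        raise ParameterError("diameter_px must be positive")
    rows, cols = spatial_shape
    rr, cc = np.ogrid[:rows, :cols]
    cr, ccol = center
    dist2 = (rr - cr) ** 2 + (cc - ccol) ** 2
    excluded = dist2 > (diameter_px / 2.0) ** 2
    reason = np.where(excluded, REASON_USER, REASON_NONE).astype(np.uint8)
    return PixelMask(excluded, reason)
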