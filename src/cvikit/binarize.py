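"""Binarization of EDI-OCT B-scans into dark (luminal) and light (stromal) pixels.

The choroidal vascularity index rests on a single image-processing decision:
which pixels of the grayscale B-scan count as *dark*. Dark pixels are read as
vessel lumens, light pixels as stroma. Three thresholding schemes are
provided:

* Niblack's auto-local threshold (the default for CVI work): a pixel is dark
  when its intensity falls below ``mean + k * std`` computed over a square
  sliding window. With the dark-object convention ``k < 0`` the threshold
  sits below the local mean, so only clearly dark structures are selected.
* Otsu's global threshold: maximizes between-class variance over a 256-bin
  histogram of the whole image.
* Bernsen's local threshold: the midrange ``(local min + local max) / 2``,
  with a contrast floor below which a pixel is assigned a fixed label.

All three use reflect padding at the image borders (edge pixel not
duplicated) and a strict ``<`` comparison, so ties are light. Results are
deterministic and bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "PixelScale",
    "BScan",
    "ThresholdParams",
    "BinaryMask",
    "niblack_binarize",
    "otsu_binarize",
    "bernsen_binarize",
    "binarize",
    "load_bscan",
    "save_mask",
]

# Sliding-window border convention shared by the local thresholders:
# edge-excluding reflection, i.e. numpy.pad(mode="reflect"), which is
# scipy.ndimage mode="mirror".
_PAD_MODE = "mirror"

# Tie guard on the strict-< dark test for statistics-based thresholds:
# intensities exactly at the threshold in exact arithmetic must classify
# light no matter how the window mean was rounded. 1e-9 is far above the
# ~1e-13 accumulation error of windowed sums on [0, 1] data and far below
# any real intensity contrast.
TIE_TOL = 1e-9

DEFAULT_WINDOW_RADIUS_PX = 15
DEFAULT_NIBLACK_K = -0.2


@dataclass(frozen=True)
class PixelScale:
    """Physical size of one pixel.

    Parameters
    ----------
    lateral_um_per_px : float
        Micrometres per pixel along the B-scan (column) direction.
    axial_um_per_px : float
        Micrometres per pixel in depth (row direction).
    """

    lateral_um_per_px: float
    axial_um_per_px: float

    def __post_init__(self) -> None:
        if not (self.lateral_um_per_px > 0 and self.axial_um_per_px > 0):
            raise ValueError(
                "pixel scales must be strictly positive, got "
                f"lateral={self.lateral_um_per_px}, axial={self.axial_um_per_px}"
            )

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one pixel in mm² (µm² × 1e-6)."""
        return self.lateral_um_per_px * self.axial_um_per_px * 1e-6

    @classmethod
    def from_scan_length(cls, scan_length_mm: float, width_px: int,
                         axial_um_per_px: float) -> "PixelScale":
        """Derive the lateral scale from a known scan length.

        EDI-OCT raster lines have a fixed physical length (e.g. 8.9 mm on a
        30° Spectralis line scan); dividing by the image width gives the
        lateral pitch. The axial pitch must always be supplied by the device.
        """
        return cls(lateral_um_per_px=scan_length_mm * 1000.0 / width_px,
                   axial_um_per_px=axial_um_per_px)


@dataclass(frozen=True)
class BScan:
    """A grayscale OCT B-scan with physical pixel scale.

    ``pixels`` holds intensities normalized to [0, 1]; row 0 is the top of
    the image and rows increase with depth.
    """

    pixels: np.ndarray
    scale: PixelScale

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"B-scan must be 2-D with at least 2x2 pixels, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("B-scan contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("B-scan intensities must lie in [0, 1]; normalize at load time")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ThresholdParams:
    """Configuration of the dark/light threshold.

    ``k`` follows the dark-object convention: the Niblack threshold is
    ``mean + k * std``, so negative ``k`` pushes the threshold below the
    local mean. ``bernsen_contrast`` is the minimum local (max - min)
    contrast for Bernsen's midrange rule to apply; below it the pixel takes
    ``low_contrast_label``.
    """

    method: Literal["niblack", "otsu", "bernsen"] = "niblack"
    window_radius_px: int = DEFAULT_WINDOW_RADIUS_PX
    k: float = DEFAULT_NIBLACK_K
    bernsen_contrast: float = 0.1
    low_contrast_label: Literal["dark", "light"] = "light"

    def __post_init__(self) -> None:
        if self.method not in ("niblack", "otsu", "bernsen"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if int(self.window_radius_px) != self.window_radius_px or self.window_radius_px < 1:
            raise ValueError(f"window_radius_px must be an integer >= 1, got {self.window_radius_px}")
        if not (0.0 <= self.bernsen_contrast <= 1.0):
            raise ValueError(f"bernsen_contrast must be in [0, 1], got {self.bernsen_contrast}")
        if self.low_contrast_label not in ("dark", "light"):
            raise ValueError(f"low_contrast_label must be 'dark' or 'light', got {self.low_contrast_label}")

    @property
    def window_side(self) -> int:
        return 2 * int(self.window_radius_px) + 1


@dataclass(frozen=True)
class BinaryMask:
    """Boolean dark-pixel mask; True marks dark (luminal) pixels."""

    dark: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dark)
        if d.ndim != 2 or d.dtype != bool:
            raise ValueError("mask must be a 2-D boolean array")
        object.__setattr__(self, "dark", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dark.shape


def _check_window(image: BScan, params: ThresholdParams) -> None:
    side = params.window_side
    rows, cols = image.shape
    if side > rows or side > cols:
        raise ValueError(
            f"window side {side} px exceeds image shape {image.shape}; "
            "reduce window_radius_px or supply a larger scan"
        )


def niblack_binarize(image: BScan, params: ThresholdParams) -> BinaryMask:
    """Niblack auto-local threshold: dark iff intensity < local mean + k·std.

    Local statistics are taken over the square window of side
    ``2 * window_radius_px + 1`` centred on each pixel, with reflect padding
    at the borders. Ties (intensity exactly at threshold) are light.
    """
    if params.method != "niblack":
        raise ValueError(f"params.method is {params.method!r}, expected 'niblack'")
    _check_window(image, params)
    side = params.window_side
    px = image.pixels
    mean = ndimage.uniform_filter(px, size=side, mode=_PAD_MODE)
    sq_mean = ndimage.uniform_filter(px * px, size=side, mode=_PAD_MODE)
    var = np.maximum(sq_mean - mean * mean, 0.0)
    thresh = mean + params.k * np.sqrt(var)
    return BinaryMask(dark=px < thresh - TIE_TOL)


def otsu_binarize(image: BScan) -> BinaryMask:
    """Otsu global threshold over a 256-bin histogram; dark iff strictly below.

    Raises ``ValueError`` on a constant image, where no two classes exist.
    """
    px = image.pixels
    if np.all(px == px.flat[0]):
        raise ValueError("Otsu threshold undefined: image is constant (single intensity class)")
    t = threshold_otsu(px, nbins=256)
    return BinaryMask(dark=px < t)


def bernsen_binarize(image: BScan, params: ThresholdParams) -> BinaryMask:
    """Bernsen local midrange threshold with a contrast floor.

    Within each window the threshold is ``(min + max) / 2``; where the local
    contrast ``max - min`` falls below ``params.bernsen_contrast`` the pixel
    is assigned ``params.low_contrast_label`` outright.
    """
    if params.method != "bernsen":
        raise ValueError(f"params.method is {params.method!r}, expected 'bernsen'")
    _check_window(image, params)
    side = params.window_side
    px = image.pixels
    lo = ndimage.minimum_filter(px, size=side, mode=_PAD_MODE)
    hi = ndimage.maximum_filter(px, size=side, mode=_PAD_MODE)
    contrast = hi - lo
    midrange = (lo + hi) / 2.0
    dark = px < midrange
    low_contrast = contrast < params.bernsen_contrast
    dark[low_contrast] = params.low_contrast_label == "dark"
    return BinaryMask(dark=dark)


def binarize(image: BScan, params: ThresholdParams) -> BinaryMask:
    """Dispatch to the thresholder named by ``params.method``."""
    if params.method == "niblack":
        return niblack_binarize(image, params)
    if params.method == "otsu":
        return otsu_binarize(image)
    return bernsen_binarize(image, params)


# ---------------------------------------------------------------------------
# Image I/O

def load_bscan(path, scale: PixelScale | None = None, *,
               scan_length_mm: float | None = None,
               axial_um_per_px: float | None = None) -> BScan:
    """Load a single-channel PNG/TIFF (8- or 16-bit) as a [0, 1] B-scan.

    Intensities are normalized by the full range of the source bit depth so
    that thresholding is per-image and independent of container encoding.
    Supply either an explicit ``scale``, or ``scan_length_mm`` plus
    ``axial_um_per_px`` to derive the lateral pitch from the image width.
    """
    from PIL import Image

    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "I", "F"):
            im = im.convert("L")
        arr = np.asarray(im, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: image contains non-finite values")
    # Normalize by container bit depth (8- or 16-bit integer ranges); float
    # inputs are assumed already in [0, 1].
    if arr.max() > 1.0:
        denom = 65535.0 if arr.max() > 255.0 else 255.0
        arr = arr / denom
    arr = np.clip(arr, 0.0, 1.0)
    if scale is None:
        if scan_length_mm is None or axial_um_per_px is None:
            raise ValueError("supply a PixelScale, or scan_length_mm and axial_um_per_px")
        scale = PixelScale.from_scan_length(scan_length_mm, arr.shape[1], axial_um_per_px)
    return BScan(pixels=arr, scale=scale)


def save_mask(mask: BinaryMask, path) -> None:
    """Write a dark-pixel mask as an 8-bit PNG/TIFF (dark = 0, light = 255)."""
    from PIL import Image

    img = np.where(mask.dark, 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)
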