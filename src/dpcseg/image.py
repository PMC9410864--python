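"""Image I/O, color-space handling and the scaled 5-D feature space.

Every downstream stage works on points of the form (x, y, l, a, b): the
superpixel centroid coordinates and its mean CIELAB color, jointly rescaled
so that spatial and chromatic axes are commensurable.  Spatial coordinates
are divided by ``h_s`` and color coordinates by ``h_r``; shrinking either
divisor stretches the corresponding axes and raises the local point density
along them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage import color as skcolor

__all__ = [
    "ImageRaster",
    "FeatureVector",
    "ScalingConfig",
    "FormatError",
    "ModeError",
    "load_image",
    "save_image",
    "rgb_to_lab",
    "gray_to_lab",
    "to_lab",
    "scale_features",
    "load_label_mask",
    "save_label_mask",
]


class FormatError(ValueError):
    """Raised for images with an unsupported layout or channel count."""


class ModeError(ValueError):
    """Raised when an operation receives a raster in the wrong color mode."""


@dataclass
class ImageRaster:
    """A 2-D intensity grid in one of three modes.

    ``gray``: H×W values in [0, 255].  ``rgb``: H×W×3 values in [0, 255].
    ``lab``: H×W×3 CIELAB floats (L in [0, 100], a/b roughly [-128, 127]).
    """

    pixels: np.ndarray
    mode: str = "gray"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.mode not in ("gray", "rgb", "lab"):
            raise ModeError(f"unknown mode {self.mode!r}")
        if self.mode == "gray":
            if self.pixels.ndim != 2:
                raise FormatError("gray raster must be 2-D")
        elif self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(f"{self.mode} raster must be H×W×3")
        if self.height < 1 or self.width < 1:
            raise FormatError("raster must contain at least one pixel")
        if self.mode in ("gray", "rgb"):
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < 0 or hi > 255:
                raise FormatError(
                    f"{self.mode} values must lie in [0, 255], got [{lo}, {hi}]"
                )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class FeatureVector:
    """One clustering point: scaled (row, col) position and Lab color."""

    x: float
    y: float
    l: float
    a: float
    b: float

    def __post_init__(self) -> None:
        vals = (self.x, self.y, self.l, self.a, self.b)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite feature vector {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.l, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class ScalingConfig:
    """Divisors for the joint (space, color) rescaling.

    ``h_s`` divides pixel coordinates, ``h_r`` divides Lab channels.  The
    pipeline defaults ``h_s`` to the superpixel grid spacing S, so adjacent
    superpixels sit roughly one unit apart, and ``h_r`` to 1 (native Lab
    units).
    """

    h_s: float = 1.0
    h_r: float = 1.0

    def __post_init__(self) -> None:
        if not (self.h_s > 0 and self.h_r > 0):
            raise ValueError("scaling divisors must be positive")


def load_image(path) -> ImageRaster:
    """Read a BMP/PNG/TIFF image as a gray or rgb raster.

    16-bit inputs are rescaled onto [0, 255]; 8-bit inputs pass through
    unchanged.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise backend errors
        raise IOError(f"cannot read image file {path!s}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim == 2:
        mode = "gray"
    elif arr.ndim == 3 and arr.shape[2] == 3:
        mode = "rgb"
    else:
        raise FormatError(
            f"unsupported channel layout {arr.shape} in {path!s}; "
            "expected single-channel or 3-channel"
        )
    if arr.dtype == np.uint16:
        arr = (arr.astype(np.float64) * (255.0 / 65535.0)).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.asarray(arr, dtype=np.float64), 0, 255).round().astype(np.uint8)
    return ImageRaster(arr, mode)


def save_image(raster: ImageRaster, path) -> None:
    """Write an 8-bit gray or rgb raster (format chosen from the suffix)."""
    if raster.mode == "lab":
        raise ModeError("convert lab rasters back to rgb before saving")
    arr = np.clip(np.asarray(raster.pixels, dtype=np.float64), 0, 255)
    iio.imwrite(path, arr.round().astype(np.uint8))


def rgb_to_lab(raster: ImageRaster) -> ImageRaster:
    """Convert an rgb raster to CIELAB (sRGB primaries, D65 white point)."""
    if raster.mode != "rgb":
        raise ModeError(f"rgb_to_lab requires an rgb raster, got {raster.mode!r}")
    lab = skcolor.rgb2lab(np.asarray(raster.pixels, dtype=np.float64) / 255.0)
    return ImageRaster(lab, "lab")


def lab_to_rgb(raster: ImageRaster) -> ImageRaster:
    if raster.mode != "lab":
        raise ModeError(f"lab_to_rgb requires a lab raster, got {raster.mode!r}")
    rgb = np.clip(skcolor.lab2rgb(raster.pixels) * 255.0, 0, 255)
    return ImageRaster(rgb.round().astype(np.uint8), "rgb")


def gray_to_lab(raster: ImageRaster) -> ImageRaster:
    """Embed a gray raster into the (l, a, b) layout: l = gray, a = b = 0.

    The gray value is replicated into the lightness slot in its native 8-bit
    units (no CIELAB transform).  Gray levels stay equally spaced this way;
    the concave gray-to-L* map would compress distinctions between bright
    features, which is exactly where microfeatures of interest often sit.
    """
    if raster.mode != "gray":
        raise ModeError(f"gray_to_lab requires a gray raster, got {raster.mode!r}")
    g = np.asarray(raster.pixels, dtype=np.float64)
    lab = np.zeros(g.shape + (3,), dtype=np.float64)
    lab[:, :, 0] = g
    return ImageRaster(lab, "lab")


def to_lab(raster: ImageRaster) -> ImageRaster:
    """Bring any raster into lab mode (gray rasters use the L embedding)."""
    if raster.mode == "lab":
        return raster
    if raster.mode == "rgb":
        return rgb_to_lab(raster)
    return gray_to_lab(raster)


def scale_features(centroid, lab_color, cfg: ScalingConfig) -> FeatureVector:
    """Build one (x, y, l, a, b) point: position/h_s, color/h_r."""
    row, col = centroid
    l, a, b = lab_color
    vals = np.array([row, col, l, a, b], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite inputs to scale_features: {vals}")
    return FeatureVector(
        x=vals[0] / cfg.h_s,
        y=vals[1] / cfg.h_s,
        l=vals[2] / cfg.h_r,
        a=vals[3] / cfg.h_r,
        b=vals[4] / cfg.h_r,
    )


def save_label_mask(labels: np.ndarray, path) -> None:
    """Write an integer label grid as a single-channel PNG (8/16-bit)."""
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("label masks must be non-negative")
    dtype = np.uint8 if labels.max() <= 255 else np.uint16
    iio.imwrite(path, labels.astype(dtype))


def load_label_mask(path) -> np.ndarray:
    """Read an integer label grid from a single-channel PNG."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise FormatError(f"label mask {path!s} must be single-channel")
    return arr.astype(np.int64)
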