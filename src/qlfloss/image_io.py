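"""Grayscale fluorescence image I/O and Fire-LUT pseudocolor rendering.

Intensities are kept on their native integer scale (8- or 16-bit) as real
numbers; every downstream quantity is a ratio or a difference, so the absolute
scale cancels in percent fluorescence loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ImageFormatError, ImageIOError, ParameterError

# Control points of the ImageJ "Fire" pseudocolor table (32 anchors,
# black -> blue-violet -> red -> orange -> yellow -> white), expanded to 256
# entries by linear interpolation.
_FIRE_R = [0, 0, 1, 25, 49, 73, 98, 122, 146, 162, 173, 184, 195, 207, 217, 229,
           240, 252, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255]
_FIRE_G = [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 14, 35, 57,
           79, 101, 117, 133, 147, 161, 175, 190, 205, 219, 234, 248, 255, 255, 255, 255]
_FIRE_B = [0, 61, 96, 130, 165, 192, 220, 227, 210, 181, 151, 122, 93, 64, 35, 5,
           0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 98, 160, 223, 255, 255, 255]


def fire_lut() -> np.ndarray:
    """Return the 256x3 uint8 Fire look-up table."""
    x = np.linspace(0.0, len(_FIRE_R) - 1, 256)
    xp = np.arange(len(_FIRE_R), dtype=float)
    lut = np.stack(
        [np.interp(x, xp, np.asarray(c, dtype=float)) for c in (_FIRE_R, _FIRE_G, _FIRE_B)],
        axis=1,
    )
    return np.rint(lut).astype(np.uint8)


@dataclass(frozen=True)
class FluorescenceImage:
    """A 2D grayscale fluorescence radiance field.

    Attributes
    ----------
    pixels : np.ndarray
        Float64 array of shape (height, width); intensities on the native
        integer scale of the source file.
    source_bit_depth : int
        8 or 16; controls the integer dtype used when writing.
    """

    pixels: np.ndarray
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 3 or px.shape[1] < 3:
            raise ImageFormatError("image must be 2D with height >= 3 and width >= 3")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ImageFormatError("intensities must be finite and non-negative")
        if self.source_bit_depth not in (8, 16):
            raise ImageFormatError("source_bit_depth must be 8 or 16")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str | Path) -> FluorescenceImage:
    """Read a grayscale 8/16-bit PNG or TIFF.

    Color (multi-channel) images are rejected rather than converted: any
    channel-mixing rule would silently change loss values.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise ImageIOError(f"image file not found: {path}") from None
    except Exception as exc:  # noqa: BLE001 - plugin-specific error types
        raise ImageIOError(f"could not read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ImageFormatError(
            f"{path} has {arr.ndim} dimensions / multiple channels; "
            "convert it to single-channel grayscale first"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ImageFormatError(f"{path}: unsupported pixel type {arr.dtype}; expected uint8 or uint16")
    return FluorescenceImage(pixels=arr.astype(np.float64), source_bit_depth=depth)


def save_image(image: FluorescenceImage, path: str | Path) -> None:
    """Write an image as PNG or TIFF at its source bit depth.

    Intensities are rounded to the nearest integer and clipped to the valid
    range, so integer-valued images round-trip losslessly.
    """
    path = Path(path)
    vmax = 2 ** image.source_bit_depth - 1
    dtype = np.uint8 if image.source_bit_depth == 8 else np.uint16
    arr = np.clip(np.rint(image.pixels), 0, vmax).astype(dtype)
    try:
        iio.imwrite(path, arr)
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"could not write image {path}: {exc}") from exc


def percent_to_lut_index(percent: np.ndarray, max_percent: float) -> np.ndarray:
    """Clip percent values to [0, max_percent] and map linearly to 0..255."""
    if not max_percent > 0:
        raise ParameterError("max_percent must be > 0")
    p = np.clip(np.asarray(percent, dtype=np.float64), 0.0, max_percent)
    return np.rint(p / max_percent * 255.0).astype(np.intp)


def render_fire_lut(
    percent_loss: np.ndarray,
    max_percent: float,
    valid_mask: np.ndarray | None = None,
    scale_bar_width: int = 16,
) -> np.ndarray:
    """Render a percent-loss map through the Fire LUT.

    Pixels outside ``valid_mask`` (the ROI interior) are black.  A vertical
    color-scale bar (max_percent at the top, 0 at the bottom) is appended on
    the right, separated by a 2-pixel black gutter.

    Returns an RGB uint8 array of shape (H, W + gutter + scale_bar_width, 3).
    """
    percent_loss = np.asarray(percent_loss, dtype=np.float64)
    if percent_loss.ndim != 2:
        raise ParameterError("percent_loss must be a 2D grid")
    finite = np.isfinite(percent_loss)
    if valid_mask is None:
        valid_mask = finite
    else:
        valid_mask = np.asarray(valid_mask, dtype=bool) & finite
    lut = fire_lut()
    idx = percent_to_lut_index(np.where(valid_mask, percent_loss, 0.0), max_percent)
    rgb = lut[idx]
    rgb[~valid_mask] = 0

    h = percent_loss.shape[0]
    bar_vals = np.linspace(max_percent, 0.0, h)[:, None].repeat(scale_bar_width, axis=1)
    bar = lut[percent_to_lut_index(bar_vals, max_percent)]
    gutter = np.zeros((h, 2, 3), dtype=np.uint8)
    return np.concatenate([rgb, gutter, bar], axis=1)
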