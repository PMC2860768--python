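"""Two-step two-dimensional linear interpolation of sound-enamel fluorescence.

The sound (lesion-free) fluorescence value at an interior pixel M is
reconstructed from border anchors only:

step 1 (horizontal): L_M(x) interpolates linearly between the left and right
    border anchors g, h on M's row,
        L_M(x) = L_g + (L_h - L_g) * (X_M - X_g) / (X_h - X_g);
step 2 (vertical residual): at the top and bottom column anchors e, f the same
    horizontal rule is applied along their own rows, giving interpolated
    values L_e(i), L_f(i); the residuals dL_e = L_e - L_e(i) and
    dL_f = L_f - L_f(i) are interpolated vertically,
        L_M(y) = dL_e + (dL_f - dL_e) * (Y_M - Y_e) / (Y_f - Y_e),
    and the reconstruction is L_M(i) = L_M(x) + L_M(y).

Loss at M is dL_M = L_M(i) - L_M (observed), reported as percent of the
reconstructed sound value.  Both steps reproduce affine intensity fields
exactly, so the reconstruction is unbiased wherever sound enamel varies
(locally) linearly.

Two forms are exposed: ``interpolate_rectangle`` is the original axis-aligned
rectangle algorithm on raw edge intensities (the faithful reference form);
``interpolate_polygon`` generalizes the anchors to an arbitrary simple polygon
and uses 3x3-smoothed border intensities.  For a rectangular polygon the two
coincide wherever smoothing is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, GeometryError
from .image_io import FluorescenceImage
from .roi_geometry import RasterizedROI


@dataclass(frozen=True)
class LossMap:
    """Per-pixel reconstruction and fluorescence loss over a ROI interior.

    Grids are full-image-shaped with NaN outside ``valid_mask``.  ``percent``
    is additionally NaN where the reconstructed sound value is <= 0 (those
    pixels are dropped from ``valid_mask``).
    """

    sound: np.ndarray
    delta: np.ndarray
    percent: np.ndarray
    valid_mask: np.ndarray

    def to_dataframe(self, observed: np.ndarray | None = None) -> pd.DataFrame:
        """Interior pixel records as a tidy table (x, y, sound, delta, percent)."""
        ys, xs = np.nonzero(self.valid_mask)
        cols = {
            "x": xs,
            "y": ys,
            "sound": self.sound[ys, xs],
            "delta": self.delta[ys, xs],
            "percent": self.percent[ys, xs],
        }
        if observed is not None:
            cols["observed"] = np.asarray(observed)[ys, xs]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path, observed: np.ndarray | None = None) -> None:
        self.to_dataframe(observed).to_csv(path, index=False)


def _finalize(sound: np.ndarray, observed: np.ndarray, mask: np.ndarray) -> LossMap:
    delta = np.where(mask, sound - observed, np.nan)
    valid = mask & (sound > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(valid, 100.0 * delta / sound, np.nan)
    sound_out = np.where(mask, sound, np.nan)
    return LossMap(sound=sound_out, delta=delta, percent=percent, valid_mask=valid)


def interpolate_rectangle(
    image: FluorescenceImage, rect: tuple[int, int, int, int]
) -> LossMap:
    """Reference form of the reconstruction on an axis-aligned rectangle.

    ``rect`` is (x0, y0, x1, y1) with corners A=(x0,y0), D=(x1,y0),
    B=(x0,y1), C=(x1,y1); the four edges must sit on sound tissue.  Raw
    (unsmoothed) edge intensities are used, exactly as in the original
    algorithm: step 2 computes L_e(i), L_f(i) at the top/bottom edge pixels by
    interpolating between the corner intensities A,D and B,C.
    """
    x0, y0, x1, y1 = rect
    if x0 > x1:
        x0, x1 = x1, x0
    if y0 > y1:
        y0, y1 = y1, y0
    h, w = image.pixels.shape
    if x0 < 0 or y0 < 0 or x1 > w - 1 or y1 > h - 1:
        raise GeometryError("rectangle exceeds image bounds")
    if x1 - x0 < 2 or y1 - y0 < 2:
        raise GeometryError("rectangle must be at least 3x3 pixels to have an interior")

    px = image.pixels
    xs = np.arange(x0 + 1, x1, dtype=np.float64)  # interior columns
    ys = np.arange(y0 + 1, y1, dtype=np.float64)  # interior rows
    fx = (xs - x0) / (x1 - x0)
    fy = ((ys - y0) / (y1 - y0))[:, None]

    # step 1 on every interior row
    lg = px[y0 + 1:y1, x0][:, None]
    lh = px[y0 + 1:y1, x1][:, None]
    lmx = lg + (lh - lg) * fx[None, :]

    # step 2: residuals at the top (e, row y0) and bottom (f, row y1) edges
    le_i = px[y0, x0] + (px[y0, x1] - px[y0, x0]) * fx
    lf_i = px[y1, x0] + (px[y1, x1] - px[y1, x0]) * fx
    dle = px[y0, x0 + 1:x1] - le_i
    dlf = px[y1, x0 + 1:x1] - lf_i
    lmy = dle[None, :] + (dlf - dle)[None, :] * fy

    sound = np.full((h, w), np.nan)
    sound[y0 + 1:y1, x0 + 1:x1] = lmx + lmy
    mask = np.zeros((h, w), dtype=bool)
    mask[y0 + 1:y1, x0 + 1:x1] = True
    return _finalize(sound, px, mask)


def _horizontal_at_border(raster: RasterizedROI, sm: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Step-1 interpolation evaluated at border pixels (ys, xs).

    The anchors are the endpoints of the contiguous border run the pixel
    belongs to on its row (for a rectangle's top/bottom edge these are the
    corners, recovering the original step 2 exactly).  A single-pixel run
    yields the pixel's own value, i.e. a zero residual.
    """
    a = raster.run_start[ys, xs].astype(np.float64)
    b = raster.run_end[ys, xs].astype(np.float64)
    la = sm[ys, raster.run_start[ys, xs]]
    lb = sm[ys, raster.run_end[ys, xs]]
    span = b - a
    frac = np.where(span > 0, (xs - a) / np.where(span > 0, span, 1.0), 0.0)
    return la + (lb - la) * frac


def interpolate_polygon(
    image: FluorescenceImage,
    raster: RasterizedROI,
    border_values: np.ndarray,
) -> LossMap:
    """Polygon generalization of the two-step reconstruction.

    Row anchors g, h are each interior pixel's span anchors carrying the
    3x3-smoothed border intensities in ``border_values``; column anchors e, f
    are its column-span anchors, whose horizontal interpolations L_e(i),
    L_f(i) are computed along their own rows with the same rule.
    """
    if image.pixels.shape != raster.shape:
        raise ConsistencyError("image and raster shapes differ")
    border_values = np.asarray(border_values, dtype=np.float64)
    if border_values.shape != raster.shape:
        raise ConsistencyError("border_values grid must match the raster shape")

    mask = raster.interior_mask
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise GeometryError("raster has no interior pixels")
    if (
        np.any(raster.left_x[ys, xs] < 0)
        or np.any(raster.right_x[ys, xs] < 0)
        or np.any(raster.top_y[ys, xs] < 0)
        or np.any(raster.bottom_y[ys, xs] < 0)
    ):
        raise ConsistencyError("an interior pixel lacks its four border anchors")

    sm = border_values
    gx = raster.left_x[ys, xs]
    hx = raster.right_x[ys, xs]
    ey = raster.top_y[ys, xs]
    fy = raster.bottom_y[ys, xs]

    lg = sm[ys, gx]
    lh = sm[ys, hx]
    lmx = lg + (lh - lg) * (xs - gx) / (hx - gx)

    dle = sm[ey, xs] - _horizontal_at_border(raster, sm, ey, xs)
    dlf = sm[fy, xs] - _horizontal_at_border(raster, sm, fy, xs)
    lmy = dle + (dlf - dle) * (ys - ey) / (fy - ey)

    sound = np.full(raster.shape, np.nan)
    sound[ys, xs] = lmx + lmy
    return _finalize(sound, image.pixels, mask)
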