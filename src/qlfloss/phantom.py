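"""Synthetic QLF tooth phantoms with known ground-truth loss profiles.

A phantom is a smooth sound-fluorescence field (constant, affine, or a gentle
quadratic dome emulating natural tooth-surface curvature) with an embedded
elliptical lesion whose percent loss follows a cosine taper, plus optional
additive Gaussian sensor noise and single-pixel hot/cold spots.  The lesion is
multiplicative — observed = sound · (1 - loss/100) — so the percent-loss
ground truth is exact by construction even on curved fields.

The phantom carries its own ground truth and a suggested octagonal ROI on
sound tissue, making it the end-to-end oracle for the reconstruction and the
robust maximum-loss estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .image_io import FluorescenceImage
from .roi_geometry import PolygonROI


@dataclass(frozen=True)
class ConstantField:
    level: float = 170.0

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(x, dtype=np.float64), self.level)


@dataclass(frozen=True)
class AffineField:
    """sound(x, y) = base + gx·x + gy·y (intensity units, per pixel)."""

    base: float = 170.0
    gx: float = 0.2
    gy: float = 0.15

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.base + self.gx * np.asarray(x, float) + self.gy * np.asarray(y, float)


@dataclass(frozen=True)
class DomeField:
    """Quadratic dome peaking at the image center: the simplest stand-in for
    natural surface curvature, which stresses the linear-interpolation bias."""

    peak: float = 190.0
    droop: float = 40.0  # intensity drop from center to the farthest corner

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        cx, cy = x.mean(), y.mean()
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        return self.peak - self.droop * r2 / r2.max()


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom study conditions.

    Defaults describe a typical incipient smooth-surface lesion on an 8-bit
    QLF capture: sound enamel around 170 intensity units with a mild affine
    trend, a 15-pixel-radius lesion losing 25% fluorescence at its center,
    and unit-variance Gaussian sensor noise.
    """

    height: int = 80
    width: int = 80
    sound_field: ConstantField | AffineField | DomeField = field(default_factory=AffineField)
    lesion_center: tuple[float, float] = (40.0, 40.0)  # (x, y)
    lesion_radii: tuple[float, float] = (15.0, 15.0)   # (rx, ry)
    peak_percent: float = 25.0
    noise_sd: float = 1.0
    spike_spots: tuple[tuple[int, int, float, int], ...] = ()  # (x, y, magnitude, sign)
    roi_margin: float = 4.0
    seed: int = 0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.peak_percent < 100.0:
            raise ParameterError("peak_percent must be in (0, 100)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        cx, cy = self.lesion_center
        rx, ry = self.lesion_radii
        # a valid ROI on sound tissue must exist: lesion + ROI margin + 3 px
        pad = self.roi_margin + 3
        if (
            cx - rx - pad < 0
            or cx + rx + pad > self.width - 1
            or cy - ry - pad < 0
            or cy + ry + pad > self.height - 1
        ):
            raise ParameterError(
                "lesion must fit inside the image with the ROI margin plus a 3-pixel sound border"
            )


def _cosine_taper(rho: np.ndarray) -> np.ndarray:
    """Smooth compactly supported radial profile: 1 at center, 0 at rho >= 1."""
    return np.where(rho < 1.0, 0.5 * (1.0 + np.cos(np.pi * np.clip(rho, 0.0, 1.0))), 0.0)


def suggested_roi(spec: PhantomSpec) -> PolygonROI:
    """Octagon on sound tissue enclosing the lesion with the spec's margin."""
    cx, cy = spec.lesion_center
    wx = spec.lesion_radii[0] + spec.roi_margin
    wy = spec.lesion_radii[1] + spec.roi_margin
    c = 0.35 * min(wx, wy)  # corner cut
    verts = [
        (cx - wx + c, cy - wy),
        (cx + wx - c, cy - wy),
        (cx + wx, cy - wy + c),
        (cx + wx, cy + wy - c),
        (cx + wx - c, cy + wy),
        (cx - wx + c, cy + wy),
        (cx - wx, cy + wy - c),
        (cx - wx, cy - wy + c),
    ]
    return PolygonROI(vertices=np.asarray(verts, dtype=np.float64))


def generate_phantom(spec: PhantomSpec) -> tuple[FluorescenceImage, np.ndarray, PolygonROI]:
    """Render a phantom: (image, ground-truth percent-loss grid, suggested ROI).

    Deterministic given ``spec.seed``.
    """
    ys, xs = np.mgrid[0:spec.height, 0:spec.width]
    sound = spec.sound_field.evaluate(xs, ys)
    if np.any(sound <= 0):
        raise ParameterError("sound field must be strictly positive everywhere")

    cx, cy = spec.lesion_center
    rx, ry = spec.lesion_radii
    rho = np.sqrt(((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2)
    truth_percent = spec.peak_percent * _cosine_taper(rho)

    rng = np.random.default_rng(spec.seed)
    image = sound * (1.0 - truth_percent / 100.0)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    for sx, sy, mag, sign in spec.spike_spots:
        if not (0 <= sx < spec.width and 0 <= sy < spec.height):
            raise ParameterError(f"spike spot ({sx}, {sy}) outside the image")
        image[sy, sx] += (1 if sign >= 0 else -1) * abs(mag)

    vmax = 2 ** spec.bit_depth - 1
    image = np.clip(image, 0.0, vmax)
    return (
        FluorescenceImage(pixels=image, source_bit_depth=spec.bit_depth),
        truth_percent,
        suggested_roi(spec),
    )
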