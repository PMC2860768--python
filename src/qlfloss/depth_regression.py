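"""Linear calibration between demineralization depth and percent fluorescence loss.

Percent fluorescence loss Y (%) is regressed on histological lesion depth X
(µm) by ordinary least squares, with the full simple-regression inference
(Pearson r, slope t-test with n-2 df, model F-test with (1, n-2) df; F = t²
algebraically).  Depth is then estimated from a measured loss by inverse
prediction, with the standard calibration interval

    x̂ = (y0 - b) / m,
    x̂ ± t_{α/2, n-2} · (s/|m|) · sqrt(1 + 1/n + (x̂ - x̄)² / Sxx).

The packaged reference dataset holds six (depth µm, percent loss) pairs from
demineralized extracted molars whose lesion depths were measured on sections
under polarized light microscopy; it is the default calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError

_FIXTURE = "calibration_depth_loss.csv"


@dataclass(frozen=True)
class CalibrationData:
    """Paired (depth µm, percent loss) calibration observations."""

    depth_um: np.ndarray
    loss_percent: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_um, dtype=np.float64)
        l = np.asarray(self.loss_percent, dtype=np.float64)
        if d.ndim != 1 or d.shape != l.shape:
            raise CalibrationError("depth and loss must be 1D arrays of equal length")
        if d.size < 3:
            raise CalibrationError("at least 3 calibration pairs are required")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(l))):
            raise CalibrationError("calibration values must be finite")
        if np.any(d <= 0) or np.any(l <= 0):
            raise CalibrationError("calibration values must be positive")
        object.__setattr__(self, "depth_um", d)
        object.__setattr__(self, "loss_percent", l)

    @property
    def n(self) -> int:
        return int(self.depth_um.size)


@dataclass(frozen=True)
class DepthCalibration:
    """Fitted line loss = slope·depth + intercept with full inference."""

    slope: float            # % per µm
    intercept: float        # %
    r: float                # Pearson correlation
    t_slope: float          # slope / SE(slope), df = n - 2
    F: float                # model F, df (1, n - 2)
    p_t: float              # two-tailed
    p_F: float
    residual_se: float      # %
    n: int
    slope_se: float
    depth_mean: float
    depth_ssx: float        # Σ (depth - mean)²

    def predict_loss(self, depth_um: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(depth_um, dtype=np.float64) + self.intercept

    def report(self) -> str:
        """Human-readable summary at conventional print precision."""
        return (
            f"n = {self.n}\n"
            f"loss(%) = {self.slope:.2f} * depth(um) + {self.intercept:.2f}\n"
            f"r = {self.r:.4f}\n"
            f"t(slope, df={self.n - 2}) = {self.t_slope:.2f}  (two-tailed p = {self.p_t:.4f})\n"
            f"F(1, {self.n - 2}) = {self.F:.2f}  (p = {self.p_F:.4f})\n"
            f"residual SE = {self.residual_se:.3f} %"
        )


@dataclass(frozen=True)
class DepthEstimate:
    """Inverse-prediction depth estimate with its calibration interval."""

    depth_um: float
    lower_um: float
    upper_um: float
    confidence: float
    out_of_range: bool


def reference_calibration_data() -> CalibrationData:
    """The packaged six-pair reference calibration dataset."""
    with resources.files("qlfloss").joinpath("data", _FIXTURE).open() as fh:
        return _from_frame(pd.read_csv(fh))


def load_calibration_csv(path: str | Path) -> CalibrationData:
    """Read a calibration CSV with columns depth_um, loss_percent."""
    return _from_frame(pd.read_csv(path))


def _from_frame(df: pd.DataFrame) -> CalibrationData:
    missing = {"depth_um", "loss_percent"} - set(df.columns)
    if missing:
        raise CalibrationError(f"calibration CSV lacks columns: {sorted(missing)}")
    return CalibrationData(
        depth_um=df["depth_um"].to_numpy(dtype=np.float64),
        loss_percent=df["loss_percent"].to_numpy(dtype=np.float64),
    )


def fit_calibration(data: CalibrationData) -> DepthCalibration:
    """Ordinary least squares of percent loss on depth, with inference."""
    x, y = data.depth_um, data.loss_percent
    if np.ptp(x) == 0:
        raise CalibrationError("depth values are all equal: degenerate design")
    lr = stats.linregress(x, y)
    n = data.n
    with np.errstate(divide="ignore"):  # perfect fits: SE(slope) = 0, t = inf
        t = lr.slope / lr.stderr if lr.stderr > 0 else np.inf * np.sign(lr.slope)
        F = t * t
    resid = y - (lr.slope * x + lr.intercept)
    residual_se = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return DepthCalibration(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r=float(lr.rvalue),
        t_slope=float(t),
        F=float(F),
        p_t=float(lr.pvalue),
        p_F=float(stats.f.sf(F, 1, n - 2)),
        residual_se=residual_se,
        n=n,
        slope_se=float(lr.stderr),
        depth_mean=float(x.mean()),
        depth_ssx=float(np.sum((x - x.mean()) ** 2)),
    )


def estimate_depth(
    calibration: DepthCalibration,
    measured_loss: float,
    confidence: float = 0.95,
) -> DepthEstimate:
    """Invert the calibration: depth for a measured percent loss.

    Uses the standard approximate inverse-prediction interval for a single
    new observation.  A negative point estimate (loss below the intercept) is
    returned with an out-of-calibration-range warning rather than clipped.
    """
    if calibration.slope == 0:
        raise CalibrationError("calibration slope is zero: not invertible")
    if measured_loss < 0:
        raise CalibrationError("measured_loss must be >= 0")
    if not 0 < confidence < 1:
        raise CalibrationError("confidence must be in (0, 1)")
    x_hat = (measured_loss - calibration.intercept) / calibration.slope
    tcrit = stats.t.ppf(0.5 + confidence / 2, calibration.n - 2)
    se = (
        calibration.residual_se
        / abs(calibration.slope)
        * np.sqrt(1 + 1 / calibration.n + (x_hat - calibration.depth_mean) ** 2 / calibration.depth_ssx)
    )
    out_of_range = x_hat < 0
    if out_of_range:
        warnings.warn(
            f"estimated depth {x_hat:.2f} um is negative: the measured loss lies "
            "below the calibration range",
            stacklevel=2,
        )
    return DepthEstimate(
        depth_um=float(x_hat),
        lower_um=float(x_hat - tcrit * se),
        upper_um=float(x_hat + tcrit * se),
        confidence=confidence,
        out_of_range=out_of_range,
    )
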