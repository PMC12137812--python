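"""Evaluation statistics: MAE, RMSE, R2, Huber, SSIM, PSNR, Bland-Altman."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "MetricsReport",
    "BlandAltman",
    "huber",
    "regression_metrics",
    "image_metrics",
    "bland_altman",
]


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    r2: float
    huber: float
    n: int
    r2_defined: bool = True


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int


def huber(residual: np.ndarray | float, delta: float = 1.0) -> np.ndarray | float:
    """Elementwise Huber loss: 0.5 r^2 for |r| <= delta, else delta(|r| - delta/2)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.asarray(residual, dtype=np.float64)
    a = np.abs(r)
    out = np.where(a <= delta, 0.5 * r * r, delta * (a - 0.5 * delta))
    return float(out) if out.ndim == 0 else out


def regression_metrics(y_true, y_pred, huber_delta: float = 1.0) -> MetricsReport:
    """Standard regression metrics; R2 = 1 - SSres/SStot.

    When y_true is constant (SStot = 0), R2 is undefined and reported as nan
    with ``r2_defined=False``.
    """
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    resid = y_pred - y_true
    mae = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid**2).mean()))
    hub = float(np.mean(huber(resid, huber_delta)))
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        return MetricsReport(mae, rmse, float("nan"), hub, y_true.size, r2_defined=False)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return MetricsReport(mae, rmse, r2, hub, y_true.size)


def image_metrics(img_true, img_pred, data_range: float) -> dict[str, float]:
    """SSIM (standard windowed constants), PSNR = 10 log10(range^2/MSE),
    RMSE and MAE for an image pair.  PSNR is +inf when MSE is zero."""
    img_true = np.asarray(img_true, dtype=np.float64)
    img_pred = np.asarray(img_pred, dtype=np.float64)
    if img_true.shape != img_pred.shape:
        raise ValueError("image shapes must match")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(((img_true - img_pred) ** 2).mean())
    psnr = math.inf if mse == 0 else 10.0 * math.log10(data_range**2 / mse)
    ssim = float(structural_similarity(img_true, img_pred, data_range=data_range))
    return {
        "ssim": ssim,
        "psnr": psnr,
        "rmse": math.sqrt(mse),
        "mae": float(np.abs(img_true - img_pred).mean()),
    }


def bland_altman(y_true, y_pred) -> BlandAltman:
    """Agreement summary: bias = mean(pred - true), limits of agreement at
    bias +/- 1.96 * sample standard deviation of the differences."""
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    d = y_pred - y_true
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, d.size)
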