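"""Baseline reconstructions (FBP, OSEM), calibration-curve quantification,
and scan-time / imaging-dose accounting.

OSEM uses a parallel-beam system model built from the Radon transform and
its unfiltered adjoint; the multiplicative EM update preserves
non-negativity by construction.  Dose arithmetic uses the benchtop system's
isocenter dose rate of 21.3 cGy/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon as _sk_iradon
from skimage.transform import radon as _sk_radon

from .tomo import Sinogram
from .unet import ReconImage

__all__ = [
    "CalibrationCurve",
    "DoseResult",
    "QuantReport",
    "fbp_reconstruct",
    "osem_reconstruct",
    "fit_calibration",
    "quantify_roi",
    "scan_dose",
    "DOSE_RATE_CGY_PER_MIN",
]

DOSE_RATE_CGY_PER_MIN = 21.3


def fbp_reconstruct(s: Sinogram, filter_name: str = "ramp",
                    output_size: int | None = None,
                    pixel_size: float = 0.5) -> ReconImage:
    """Parallel-beam filtered back-projection on the sinogram's stated angles."""
    if s.n_angles < 1:
        raise ValueError("need at least one angle")
    img = _sk_iradon(s.matrix.T, theta=s.angles, filter_name=filter_name,
                     circle=True, output_size=output_size)
    return ReconImage(grid=img, pixel_size=pixel_size, method="fbp")


def _forward(img: np.ndarray, angles: np.ndarray) -> np.ndarray:
    return _sk_radon(img, theta=angles, circle=True).T


def _backproject(sino_rows: np.ndarray, angles: np.ndarray, size: int) -> np.ndarray:
    bp = _sk_iradon(sino_rows.T, theta=angles, filter_name=None,
                    circle=True, output_size=size)
    return np.clip(bp, 0.0, None)


def osem_reconstruct(
    s: Sinogram,
    n_subsets: int = 5,
    n_iterations: int = 10,
    init: np.ndarray | None = None,
    pixel_size: float = 0.5,
    eps: float = 1e-12,
) -> tuple[ReconImage, list[float]]:
    """Ordered-subsets EM with a parallel-beam system model.

    Subsets partition the angle set by interleaving (subset j takes angles
    j, j+n_subsets, ...).  Returns the reconstruction and a per-iteration
    log of the relative data mismatch."""
    if np.any(s.matrix < 0):
        raise ValueError("OSEM requires a non-negative sinogram")
    n = s.n_angles
    n_subsets = min(n_subsets, n)
    size = s.matrix.shape[1]
    x = np.full((size, size), 1.0) if init is None else np.array(init, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("init must be non-negative")
    # support restricted to the inscribed circle (parallel-beam FOV)
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    fov = (xx - c) ** 2 + (yy - c) ** 2 <= (size // 2) ** 2
    x = x * fov

    subsets = [np.arange(j, n, n_subsets) for j in range(n_subsets)]
    # sensitivity images (adjoint of ones) per subset
    sens = []
    for idx in subsets:
        ones = np.ones((idx.size, size))
        sens.append(np.maximum(_backproject(ones, s.angles[idx], size), eps))

    log: list[float] = []
    for _ in range(n_iterations):
        for idx, sj in zip(subsets, sens):
            proj = _forward(x, s.angles[idx])
            ratio = s.matrix[idx] / np.maximum(proj, eps)
            x = x * _backproject(ratio, s.angles[idx], size) / sj
            x = np.clip(x, 0.0, None)
        full = _forward(x, s.angles)
        denom = max(np.abs(s.matrix).sum(), eps)
        log.append(float(np.abs(full - s.matrix).sum() / denom))
    return ReconImage(grid=x, pixel_size=pixel_size, method="osem"), log


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear-through-origin map from reconstructed intensity to wt%."""

    slope: float  # wt% per intensity unit
    fit_domain: tuple[float, float] = (0.0, float("inf"))

    def __call__(self, intensity: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(intensity, dtype=np.float64)


def fit_calibration(known_concentrations, recon_intensities) -> CalibrationCurve:
    """Least-squares linear fit through the origin:
    concentration = slope * intensity."""
    conc = np.asarray(known_concentrations, dtype=np.float64)
    inten = np.asarray(recon_intensities, dtype=np.float64)
    if conc.size != inten.size or conc.size < 2:
        raise ValueError("need at least two paired calibration points")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    ss = float((inten**2).sum())
    if ss == 0:
        raise ValueError("degenerate calibration: all intensities identical/zero")
    slope = float((inten * conc).sum() / ss)
    return CalibrationCurve(slope=slope,
                            fit_domain=(float(inten.min()), float(inten.max())))


@dataclass(frozen=True)
class QuantReport:
    roi_label: str
    mean_wtpct: float
    sd_wtpct: float
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count <= 0:
            raise ValueError("pixel_count must be positive")
        if self.sd_wtpct < 0:
            raise ValueError("sd must be non-negative")


def quantify_roi(img: ReconImage, curve: CalibrationCurve, roi: np.ndarray,
                 label: str = "roi") -> QuantReport:
    """Mean +/- sd of calibrated concentration over an ROI mask."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.grid.shape:
        raise ValueError("ROI mask shape must match the image")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    vals = np.asarray(curve(img.grid[roi]), dtype=np.float64)
    return QuantReport(roi_label=label, mean_wtpct=float(vals.mean()),
                       sd_wtpct=float(vals.std()), pixel_count=int(roi.sum()))


@dataclass(frozen=True)
class DoseResult:
    """Scan time and imaging dose.  Unrounded floats internally; the
    ``*_rounded`` fields carry 2-decimal half-up presentation values computed
    with exact decimal arithmetic from the inputs (26.625 -> 26.63)."""

    scan_time_min: float
    dose_cgy: float
    projections: int
    seconds_per_projection: float
    dose_rate: float
    scan_time_rounded: float = 0.0
    dose_rounded: float = 0.0


def scan_dose(projections: int, seconds_per_projection: float,
              dose_rate: float = DOSE_RATE_CGY_PER_MIN) -> DoseResult:
    """scan_time = projections * seconds / 60; dose = scan_time * dose_rate."""
    if projections < 0 or seconds_per_projection < 0 or dose_rate < 0:
        raise ValueError("inputs must be non-negative")
    t = projections * seconds_per_projection / 60.0
    from decimal import ROUND_HALF_UP, Decimal
    t_exact = Decimal(int(projections)) * Decimal(repr(seconds_per_projection)) / 60
    d_exact = t_exact * Decimal(repr(dose_rate))
    cents = Decimal("0.01")
    return DoseResult(scan_time_min=t, dose_cgy=t * dose_rate,
                      projections=int(projections),
                      seconds_per_projection=float(seconds_per_projection),
                      dose_rate=float(dose_rate),
                      scan_time_rounded=float(
                          t_exact.quantize(cents, rounding=ROUND_HALF_UP)),
                      dose_rounded=float(
                          d_exact.quantize(cents, rounding=ROUND_HALF_UP)))
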