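"""Ratiometric Fura-2 calibration and ratio-to-[Ca²⁺] conversion.

The background-subtracted F340/F380 ratio R maps to free calcium via

    [Ca²⁺] = K_eff · (R − R_min) / (R_max − R)

with R_min the ratio at zero Ca²⁺, R_max at saturation and K_eff the
effective dissociation constant (239.95 nM at 25 °C, pH 7.2 for the
K-gluconate internal used here).  Calibration fits the forward saturation
form R([Ca]) to measurements of EGTA-buffered standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core_io import RatioSeries

__all__ = ["FuraCalibration", "KEFF_DEFAULT_NM", "ratio_to_ca",
           "ratio_from_ca", "fit_calibration", "mean_ratio"]

#: effective dissociation constant of Fura-2 at 25 °C, pH 7.2 (nM)
KEFF_DEFAULT_NM = 239.95


@dataclass
class FuraCalibration:
    r_min: float   # ratio at zero Ca²⁺
    r_max: float   # ratio at saturating Ca²⁺
    k_eff: float = KEFF_DEFAULT_NM  # nM

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise ValueError("need r_max > r_min > 0")
        if not self.k_eff > 0:
            raise ValueError("k_eff must be > 0")


class SaturationError(ValueError):
    """Measured ratio at or above R_max: conversion undefined."""


def ratio_to_ca(calib: FuraCalibration, r, strict: bool = False):
    """Convert ratio(s) to free [Ca²⁺] in nM.

    Ratios below R_min map to 0 with a warning (measurement noise near zero
    calcium) unless ``strict``; ratios at or above R_max raise.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr >= calib.r_max):
        raise SaturationError("ratio at or above R_max; indicator saturated")
    if np.any(r_arr < calib.r_min):
        if strict:
            raise ValueError("ratio below R_min")
        warnings.warn("ratio below R_min mapped to 0 nM")
    ca = calib.k_eff * (r_arr - calib.r_min) / (calib.r_max - r_arr)
    ca = np.maximum(ca, 0.0)
    return ca if np.ndim(r) else float(ca)


def ratio_from_ca(calib: FuraCalibration, ca):
    """Forward saturation form R([Ca]) = (R_min + R_max·c/K_eff)/(1 + c/K_eff)."""
    c = np.asarray(ca, dtype=float) / calib.k_eff
    r = (calib.r_min + calib.r_max * c) / (1.0 + c)
    return r if np.ndim(ca) else float(r)


def fit_calibration(points, max_restarts: int = 5) -> tuple[FuraCalibration, dict]:
    """Fit (R_min, R_max, K_eff) to (known [Ca²⁺] nM, measured ratio) pairs.

    Operates on the forward saturation form (not a linearized transform) by
    least squares.  Requires at least 3 points spanning from near-zero toward
    saturation.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("calibration needs at least 3 (ca, ratio) points")
    ca, r = pts[:, 0], pts[:, 1]
    if np.any(ca < 0):
        raise ValueError("calcium concentrations must be >= 0")

    def model(theta):
        r_min, r_max, log_keff = theta
        c = ca / np.exp(log_keff)
        return (r_min + r_max * c) / (1.0 + c) - r

    x0 = np.array([float(r.min()), float(r.max()) * 1.2,
                   np.log(max(float(np.median(ca[ca > 0])) if np.any(ca > 0)
                              else KEFF_DEFAULT_NM, 1.0))])
    best = None
    for attempt in range(max_restarts + 1):
        start = x0 + 0.2 * attempt * np.array([-0.1, 0.5, 0.5])
        sol = optimize.least_squares(model, start, method="lm", max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost <= 1e-6 * np.sum(r ** 2) + 1e-15:
            break
    if best is None or not best.success:
        raise RuntimeError("calibration fit did not converge")
    r_min, r_max, log_keff = best.x
    if r_max <= r_min:
        raise RuntimeError("calibration fit degenerate: R_max <= R_min")
    calib = FuraCalibration(float(r_min), float(r_max), float(np.exp(log_keff)))
    diag = {"residual_norm": float(np.sqrt(2 * best.cost)),
            "n_points": int(ca.size), "success": bool(best.success)}
    return calib, diag


def mean_ratio(f340, f380, background_340: float = 0.0,
               background_380: float = 0.0) -> tuple[float, RatioSeries]:
    """Mean background-subtracted ratio over an image series.

    Images where a background meets or exceeds its signal are excluded with a
    warning; an error is raised if no image survives.
    """
    f340 = np.asarray(f340, dtype=float)
    f380 = np.asarray(f380, dtype=float)
    if f340.size != f380.size or f340.size == 0:
        raise ValueError("f340 and f380 must be equal-length, non-empty")
    good = (f340 > background_340) & (f380 > background_380)
    if not np.all(good):
        warnings.warn(f"{int(np.sum(~good))} image(s) with background >= "
                      "signal excluded")
    if not np.any(good):
        raise ValueError("all images excluded: background >= signal")
    ratios = (f340[good] - background_340) / (f380[good] - background_380)
    series = RatioSeries(ratios, n_images=int(np.sum(good)),
                         background_subtracted=True)
    return float(np.mean(ratios)), series
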