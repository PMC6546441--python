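"""Scanner linearization.

A flatbed scanner's response to reflectance is close to, but not exactly,
linear.  Scanning a set of gray standards of known reflectance gives
(reflectance, raw value) pairs per channel; a monotone polynomial fitted to
those pairs maps raw scanner values onto a linear-reflectance scale, which
all downstream colorimetry assumes.  Degree 1 is the default (the scanner
is nominally linear); higher degrees are opt-in for non-linear devices.
Calibration is per-channel; no cross-channel color matrix is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("R", "G", "B")

__all__ = ["CHANNELS", "CalibrationError", "CalibrationCurve", "fit_calibration", "apply_calibration"]


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    """Per-channel monotone polynomial mapping raw scanner values -> linear reflectance.

    ``coefficients`` maps channel name to numpy polynomial coefficients
    (highest degree first, as ``np.polyval`` expects).  ``diagnostics``
    holds per-channel R^2 and max absolute residual over the standards.
    """

    coefficients: dict
    degree: int
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def identity(cls) -> "CalibrationCurve":
        return cls({c: np.array([1.0, 0.0]) for c in CHANNELS}, degree=1)

    def map_channel(self, channel: str, values: np.ndarray) -> np.ndarray:
        return np.clip(np.polyval(self.coefficients[channel], values), 0.0, 1.0)

    def to_json(self, path) -> None:
        payload = {
            "degree": self.degree,
            "coefficients": {c: list(map(float, v)) for c, v in self.coefficients.items()},
            "diagnostics": self.diagnostics,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            payload = json.load(fh)
        coeffs = {c: np.asarray(v, dtype=float) for c, v in payload["coefficients"].items()}
        return cls(coeffs, degree=payload["degree"], diagnostics=payload.get("diagnostics", {}))


def _check_monotone(coeffs: np.ndarray) -> bool:
    grid = np.linspace(0.0, 1.0, 256)
    mapped = np.polyval(coeffs, grid)
    return bool(np.all(np.diff(mapped) >= -1e-12))


def _fit_monotone_poly(raw: np.ndarray, refl: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares polynomial raw -> reflectance, non-decreasing on [0, 1].

    Starts from the unconstrained fit; if that is non-monotone, re-solves
    with the derivative constrained >= 0 on a grid (SLSQP projection).
    """
    coeffs = np.polyfit(raw, refl, degree)
    if _check_monotone(coeffs):
        return coeffs
    from scipy.optimize import minimize

    grid = np.linspace(0.0, 1.0, 64)
    powers = np.arange(degree, -1, -1)
    A = raw[:, None] ** powers  # Vandermonde, highest degree first
    dpow = powers[:-1]  # constant term has zero derivative
    Dg = dpow * grid[:, None] ** (dpow - 1)

    def sse(c):
        r = A @ c - refl
        return float(r @ r)

    def sse_grad(c):
        return 2.0 * A.T @ (A @ c - refl)

    cons = {"type": "ineq", "fun": lambda c: Dg @ c[:-1], "jac": lambda c: np.hstack([Dg, np.zeros((len(grid), 1))])}
    res = minimize(sse, coeffs, jac=sse_grad, method="SLSQP", constraints=[cons],
                   options={"maxiter": 200, "ftol": 1e-14})
    return res.x


def fit_calibration(standards: pd.DataFrame, degree: int = 1) -> CalibrationCurve:
    """Least-squares polynomial per channel mapping raw -> known reflectance.

    ``standards`` needs columns ``channel`` (R/G/B), ``reflectance`` and
    ``raw``, both in [0, 1], with at least ``degree + 2`` distinct
    reflectance levels per channel.  Fits whose mapping decreases anywhere
    on a 256-point grid of [0, 1] are rejected.
    """
    if degree < 1:
        raise CalibrationError("degree must be >= 1")
    required = {"channel", "reflectance", "raw"}
    if not required.issubset(standards.columns):
        raise CalibrationError(f"standards table needs columns {sorted(required)}")
    vals = standards[["reflectance", "raw"]].to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise CalibrationError("reflectance and raw values must lie in [0, 1]")

    coefficients, diagnostics = {}, {}
    for channel in CHANNELS:
        sub = standards[standards["channel"] == channel]
        if sub.empty:
            raise CalibrationError(f"no standards for channel {channel}")
        raw = sub["raw"].to_numpy(dtype=float)
        refl = sub["reflectance"].to_numpy(dtype=float)
        if len(np.unique(refl)) < max(3, degree + 2):
            raise CalibrationError(
                f"channel {channel}: need >= {max(3, degree + 2)} distinct reflectance levels"
            )
        if np.ptp(raw) < 1e-9:
            raise CalibrationError(f"channel {channel}: raw values are constant (degenerate)")
        coeffs = _fit_monotone_poly(raw, refl, degree)
        if not _check_monotone(coeffs):
            raise CalibrationError(
                f"channel {channel}: fitted degree-{degree} mapping is not monotone on [0, 1]"
            )
        fitted = np.polyval(coeffs, raw)
        ss_res = float(np.sum((refl - fitted) ** 2))
        ss_tot = float(np.sum((refl - refl.mean()) ** 2))
        diagnostics[channel] = {
            "r_squared": 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot,
            "max_residual": float(np.max(np.abs(refl - fitted))),
        }
        coefficients[channel] = coeffs
    return CalibrationCurve(coefficients, degree=degree, diagnostics=diagnostics)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Scale integer images onto [0, 1] (uint8 by 255, uint16 by 65535)."""
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    if image.dtype == np.uint16:
        return image.astype(float) / 65535.0
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise CalibrationError("float images must already be scaled to [0, 1]")
    return image


def apply_calibration(image: np.ndarray, curve: CalibrationCurve) -> np.ndarray:
    """Map each channel of an RGB image through the calibration curve.

    Integer inputs are normalized first; output is float in [0, 1].
    """
    image = normalize_image(image)
    if image.ndim != 3 or image.shape[2] != len(CHANNELS):
        raise CalibrationError(f"expected an RGB image, got shape {image.shape}")
    out = np.empty_like(image)
    for k, channel in enumerate(CHANNELS):
        out[..., k] = curve.map_channel(channel, image[..., k])
    return out
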