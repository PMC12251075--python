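"""Calibration-curve generation, fitting and inversion.

A calibration curve maps dye concentration C (ug/mL) to normalized transmission
I/I0 at a fixed wavelength.  Two functional forms are supported:

* ``single_exponential``:  I/I0 = a * 10**(-b*C) + c  with a > 0, b > 0, c >= 0.
  This nests the ideal Beer-Lambert response (a = 1, c = 0, b = eps*L) and
  allows a baseline offset from stray light.
* ``linear``:  I/I0 = slope * C + intercept, a small-absorbance approximation.

Both forms are monotone decreasing over a valid calibration range, so inversion
(measured I/I0 -> concentration) is closed-form and unique.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FlowSpecError, require
from .spectra import DetectorConfig, DyeDefinition, FlowCellGeometry, transmission

MODEL_KINDS = ("single_exponential", "linear")


@dataclass(frozen=True)
class CalibrationPoint:
    """One (concentration, normalized transmission) observation at a wavelength."""

    concentration: float
    normalized_transmission: float
    wavelength: float

    def __post_init__(self):
        require(self.concentration >= 0, "negative_concentration")
        require(self.normalized_transmission > 0, "nonpositive_transmission")
        if self.normalized_transmission > 1.0:
            # Physically I/I0 <= 1; values slightly above 1 happen under noise
            # near the blank.  Flag loudly, never clip.
            warnings.warn(
                f"calibration point has I/I0 = {self.normalized_transmission:.4f} > 1",
                stacklevel=2,
            )

    @property
    def suspect(self) -> bool:
        return self.normalized_transmission > 1.0


def _exp_model(c, a, b, offset):
    return a * np.power(10.0, -b * c) + offset


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted concentration <-> transmission map at one wavelength.

    ``parameters`` is (a, b, c) for ``single_exponential`` and
    (slope, intercept) for ``linear``.
    """

    dye_name: str
    wavelength: float
    model_kind: str
    parameters: tuple
    valid_concentration_range: tuple
    fit_residual_rms: float

    def __post_init__(self):
        require(self.model_kind in MODEL_KINDS, "unknown_model_kind")
        lo, hi = self.valid_concentration_range
        require(hi > lo >= 0, "invalid_range")
        # Monotone decreasing over the valid range, and I/I0 at C = lo in (0, 1].
        grid = np.linspace(lo, hi, 257)
        pred = self.predict(grid)
        require(bool(np.all(np.diff(pred) < 0)), "nonmonotone_calibration")
        # Blank-end prediction must be a physical transmission; a small
        # allowance above 1 absorbs fit noise on the blank standards.
        require(0 < pred[0] <= 1.0 + 0.02, "invalid_blank_transmission")

    def predict(self, concentration):
        """Forward map C -> I/I0."""
        c = np.asarray(concentration, dtype=float)
        if self.model_kind == "single_exponential":
            a, b, offset = self.parameters
            out = _exp_model(c, a, b, offset)
        else:
            slope, intercept = self.parameters
            out = slope * c + intercept
        return float(out) if out.ndim == 0 else out

    def invert(self, normalized_transmission: float, tol: float = 0.005) -> float:
        """Closed-form inverse map I/I0 -> C on the valid range.

        Measured values outside the predicted range by more than ``tol``
        (absolute, in transmission units) raise ``out_of_calibration_range``;
        within ``tol`` they are clamped to the range boundary.
        """
        lo, hi = self.valid_concentration_range
        y_hi, y_lo = self.predict(lo), self.predict(hi)  # decreasing curve
        y = float(normalized_transmission)
        require(
            y_lo - tol <= y <= y_hi + tol,
            "out_of_calibration_range",
            f"I/I0 = {y:.4f} outside predicted range [{y_lo:.4f}, {y_hi:.4f}]",
        )
        y = min(max(y, y_lo), y_hi)
        if self.model_kind == "single_exponential":
            a, b, offset = self.parameters
            return float(-np.log10((y - offset) / a) / b)
        slope, intercept = self.parameters
        return float((y - intercept) / slope)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["parameters"] = list(self.parameters)
        d["valid_concentration_range"] = list(self.valid_concentration_range)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            dye_name=d["dye_name"],
            wavelength=float(d["wavelength"]),
            model_kind=d["model_kind"],
            parameters=tuple(d["parameters"]),
            valid_concentration_range=tuple(d["valid_concentration_range"]),
            fit_residual_rms=float(d["fit_residual_rms"]),
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def generate_calibration_set(
    dye: DyeDefinition,
    levels: Sequence[float],
    geometry: FlowCellGeometry,
    detector: DetectorConfig,
    replicates: int = 1,
    band_half_width: float = 0.0,
) -> list[CalibrationPoint]:
    """Forward-model single-dye standards at the dye's peak wavelength.

    For each concentration level and replicate the Beer-Lambert transmission at
    the peak wavelength is computed and multiplicative detector noise applied.
    Deterministic under a fixed ``detector.rng_seed``.
    """
    require(replicates >= 1, "invalid_replicates")
    levels = [float(v) for v in levels]
    for v in levels:
        require(v >= 0, "negative_concentration")
        require(
            v <= dye.stock_concentration,
            "above_stock",
            f"level {v} ug/mL above stock {dye.stock_concentration} ug/mL",
        )
    wl = dye.spectrum.peak_wavelength
    eps_l = dye.spectrum.absorptivity_at(wl, band_half_width) * geometry.path_length_mm
    rng = np.random.default_rng(detector.rng_seed)
    points = []
    for level in levels:
        true_t = transmission(eps_l * level)
        for _ in range(replicates):
            if detector.relative_noise_sd > 0:
                meas = true_t * (1.0 + detector.relative_noise_sd * rng.standard_normal())
                meas = max(meas, np.finfo(float).tiny)
            else:
                meas = true_t
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # >1 flag handled by .suspect
                points.append(CalibrationPoint(level, float(meas), wl))
    return points


def fit_calibration(
    points: Sequence[CalibrationPoint],
    model_kind: str = "single_exponential",
    dye_name: str | None = None,
) -> CalibrationCurve:
    """Least-squares fit of a calibration curve to measured points.

    The single-exponential fit is initialised deterministically: a = 1,
    c = half the smallest observed I/I0, and b from a log-linear regression of
    (I/I0 - c) against concentration.  Fits whose curve is not strictly
    decreasing over the data range are refused (``nonmonotone_calibration``).
    """
    require(model_kind in MODEL_KINDS, "unknown_model_kind")
    conc = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.normalized_transmission for p in points], dtype=float)
    n_min = 3 if model_kind == "single_exponential" else 2
    require(len(points) >= n_min, "insufficient_points")
    require(float(np.ptp(conc)) > 0, "insufficient_points", "concentrations all equal")
    wavelengths = {p.wavelength for p in points}
    require(len(wavelengths) == 1, "mixed_wavelengths")
    wl = wavelengths.pop()
    if dye_name is None:
        dye_name = "unknown"

    if model_kind == "linear":
        slope, intercept = np.polyfit(conc, y, 1)
        params = (float(slope), float(intercept))
        resid = y - (slope * conc + intercept)
    else:
        c0 = 0.5 * float(np.min(y))
        shifted = np.clip(y - c0, np.finfo(float).tiny, None)
        b0 = max(float(-np.polyfit(conc, np.log10(shifted), 1)[0]), 1e-6)
        try:
            popt, _ = curve_fit(
                _exp_model,
                conc,
                y,
                p0=[1.0, b0, c0],
                bounds=([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - pathological data
            raise FlowSpecError("fit_failed", str(exc)) from exc
        params = tuple(float(v) for v in popt)
        resid = y - _exp_model(conc, *popt)

    rms = float(np.sqrt(np.mean(resid**2)))
    lo, hi = float(np.min(conc)), float(np.max(conc))
    try:
        return CalibrationCurve(dye_name, float(wl), model_kind, params, (lo, hi), rms)
    except FlowSpecError as exc:
        if exc.code in ("nonmonotone_calibration", "invalid_blank_transmission"):
            raise FlowSpecError(
                "nonmonotone_calibration",
                "fitted curve is not a valid decreasing calibration on the data range",
            ) from exc
        raise


def points_to_frame(points: Sequence[CalibrationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "concentration_ug_ml": [p.concentration for p in points],
            "normalized_transmission": [p.normalized_transmission for p in points],
            "wavelength_nm": [p.wavelength for p in points],
        }
    )


def points_from_frame(df: pd.DataFrame, wavelength: float | None = None) -> list[CalibrationPoint]:
    if wavelength is None:
        if "wavelength_nm" in df.columns:
            wls = df["wavelength_nm"].to_numpy(float)
        else:
            raise FlowSpecError("mixed_wavelengths", "no wavelength column and none given")
    else:
        wls = np.full(len(df), float(wavelength))
    return [
        CalibrationPoint(float(c), float(t), float(w))
        for c, t, w in zip(
            df["concentration_ug_ml"], df["normalized_transmission"], wls
        )
    ]
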