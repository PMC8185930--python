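"""Epicuticular-wax prediction from spectral indices and band-linear models.

Two prediction routes are provided:

* **Inverse prediction from an index.**  A calibration line
  ``index = a + B * EW`` is fitted on paired (spectrum, wax) data; the wax
  load of a new sample is then the inverted line ``EW = (index - a) / B``.
  Built-in calibrations ship for all fourteen EWI indices.

* **Multivariate band models (EWM-1..7).**  Linear models
  ``EW = intercept + sum_k coef_k * rho_k`` on up to eight narrow
  wavelengths {424, 547, 574, 658, 712, 721, 775, 817} nm, reflectance on
  the fraction scale.

The built-in constants are frozen transcriptions of the published
calibration tables; re-deriving them from new data is the job of
:mod:`waxspec.calibration`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .signature import SpectralSignature, band_at

__all__ = [
    "IndexCalibration",
    "EWMModel",
    "EWM_WAVELENGTHS",
    "builtin_calibrations",
    "builtin_ewm_models",
    "predict_ew_from_index",
    "predict_ew_ewm",
    "evaluate_predictions",
    "SaturationWarning",
]

#: Narrow wavelengths (nm) the EWM models may draw coefficients from.
EWM_WAVELENGTHS = (424, 547, 574, 658, 712, 721, 775, 817)

#: EW load (mg/dm^2) above which the blue/red ratio index saturates and
#: its inverse predictions become unreliable.
EWI1_SATURATION_MG_DM2 = 6.0


class SaturationWarning(UserWarning):
    """Prediction is outside the validated wax range of the calibration."""


@dataclass(frozen=True)
class IndexCalibration:
    """Calibration line ``index = a + B * ew`` for one spectral index.

    ``a`` is the intercept (index units), ``B`` the slope (index units per
    mg/dm^2 of wax); diagnostics carry the cross-validated R^2 and the
    bootstrap RMSE (mg/dm^2) with its 95 % interval.
    """

    index_name: str
    a: float
    B: float
    r2: float | None = None
    rmse_mg_dm2: float | None = None
    ci95: tuple | None = None
    source: str = "user-fit"

    def __post_init__(self) -> None:
        if self.B == 0:
            raise ValueError("calibration slope B must be nonzero (non-invertible)")
        if self.rmse_mg_dm2 is not None and self.rmse_mg_dm2 < 0:
            raise ValueError("rmse must be >= 0")

    def predict_index(self, ew) -> np.ndarray:
        """Forward direction: expected index value at a given wax load."""
        return self.a + self.B * np.asarray(ew, dtype=float)


@dataclass(frozen=True)
class EWMModel:
    """Band-linear wax model ``EW = intercept + sum coef[nm] * rho_nm``."""

    name: str
    intercept: float
    coefficients: Mapping[int, float]
    rmse: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        coefs = dict(self.coefficients)
        object.__setattr__(self, "coefficients", coefs)
        if not coefs:
            raise ValueError("EWMModel needs at least one coefficient")
        bad = set(coefs) - set(EWM_WAVELENGTHS)
        if bad:
            raise ValueError(f"coefficient wavelengths {sorted(bad)} outside {EWM_WAVELENGTHS}")


# Frozen published calibration constants for EWI-1..14:
# (a, B, R2_loocv, RMSE mg/dm^2, 95% CI of RMSE).
_BUILTIN_CALIBRATIONS = {
    "EWI-1": (0.213, 0.04, 0.44, 1.19, (1.037, 2.17)),
    "EWI-2": (0.07, 0.13, 0.39, 1.18, (0.98, 1.98)),
    "EWI-3": (-0.93, -0.01, 0.31, 1.19, (1.04, 1.97)),
    "EWI-4": (-0.09, -0.03, 0.32, 1.19, (1.09, 2.55)),
    "EWI-5": (0.019, 0.005, 0.45, 0.97, (0.75, 1.21)),
    "EWI-6": (0.12, 0.03, 0.52, 1.02, (0.70, 1.36)),
    "EWI-7": (0.22, 0.05, 0.50, 0.96, (0.67, 1.28)),
    "EWI-8": (-0.006, -0.002, 0.42, 1.08, (0.96, 1.55)),
    "EWI-9": (-0.85, 0.03, 0.51, 1.04, (0.61, 1.54)),
    "EWI-10": (4.92, -1.03, 0.48, 0.99, (0.74, 1.27)),
    "EWI-11": (29.13, -5.73, 0.48, 1.01, (0.71, 1.35)),
    "EWI-12": (0.62, 0.12, 0.51, 0.99, (0.74, 1.28)),
    "EWI-13": (0.008, 0.004, 0.65, 1.01, (0.622, 1.426)),
    "EWI-14": (0.02, 0.007, 0.62, 0.98, (0.65, 1.35)),
}

# Frozen published EWM models: (intercept, {nm: coef}, RMSE, R2).
# The published coefficient digits are concatenated in the source table; this
# parse is pinned by the narrative R^2 (0.33, 0.45, ..., 0.71), the RMSE range
# 0.49-0.52, and dimensional plausibility on fraction-scale reflectance.
_BUILTIN_EWM = {
    "EWM-1": (0.46, {424: 52.0}, 0.49, 0.33),
    "EWM-2": (0.31, {658: 90.3, 721: -3.88}, 0.50, 0.45),
    "EWM-3": (0.71, {712: 160.7, 721: -183.1, 775: -33.7, 817: 80.2}, 0.51, 0.58),
    "EWM-4": (0.19, {658: 40.8, 712: 109.6, 721: -128.4, 775: -65.8, 817: 99.1}, 0.51, 0.60),
    "EWM-5": (-0.22, {574: 17.3, 658: 16.9, 712: 82.9, 721: -109.1, 775: -122.2, 817: 153.4},
              0.51, 0.61),
    "EWM-6": (1.13, {424: -76.4, 574: 1.9, 658: 134.7, 712: 76.4, 721: -109.9, 775: -45.1,
                     817: 78.1}, 0.52, 0.66),
    "EWM-7": (-3.1, {424: -73.5, 547: 58.9, 574: -82.7, 658: 146.9, 712: 89.6, 721: -188.8,
                     775: -91.6, 817: 134.3}, 0.52, 0.71),
}


def builtin_calibrations() -> dict[str, IndexCalibration]:
    """The 14 built-in EWI calibration lines (index = a + B * EW)."""
    return {
        name: IndexCalibration(name, a, B, r2=r2, rmse_mg_dm2=rmse, ci95=ci, source="builtin")
        for name, (a, B, r2, rmse, ci) in _BUILTIN_CALIBRATIONS.items()
    }


def builtin_ewm_models() -> dict[str, EWMModel]:
    """The 7 built-in multivariate wax models EWM-1..7."""
    return {
        name: EWMModel(name, intercept, coefs, rmse=rmse, r2=r2)
        for name, (intercept, coefs, rmse, r2) in _BUILTIN_EWM.items()
    }


def predict_ew_from_index(index_value, calib: IndexCalibration):
    """Invert a calibration line: EW = (index - a) / B, mg/dm^2.

    Predictions are not clamped; negative values and EWI-1 predictions above
    the saturation range carry a warning but are returned as computed.
    """
    index_value = np.asarray(index_value, dtype=float)
    ew = (index_value - calib.a) / calib.B
    if np.any(ew < 0):
        warnings.warn(
            f"{calib.index_name}: negative wax prediction(s); outside calibration domain",
            SaturationWarning,
            stacklevel=2,
        )
    if calib.index_name == "EWI-1" and np.any(ew > EWI1_SATURATION_MG_DM2):
        warnings.warn(
            f"EWI-1 saturates above {EWI1_SATURATION_MG_DM2} mg/dm^2; "
            "predictions beyond that are unreliable",
            SaturationWarning,
            stacklevel=2,
        )
    return float(ew) if ew.ndim == 0 else ew


def predict_ew_ewm(sig: SpectralSignature, model: EWMModel, tol: float = 2.0) -> float:
    """Evaluate a band-linear wax model on one reflectance signature."""
    total = model.intercept
    for nm, coef in model.coefficients.items():
        total += coef * band_at(sig, float(nm), tol=tol)
    if total < 0:
        warnings.warn(
            f"{model.name}: negative wax prediction ({total:.3f} mg/dm^2)",
            SaturationWarning,
            stacklevel=2,
        )
    return float(total)


def evaluate_predictions(predicted, observed) -> dict:
    """RMSE, squared Pearson R^2, and residuals of a prediction vector.

    RMSE = sqrt(mean((observed - predicted)^2)); residuals are
    observed - predicted, returned for diagnostics such as checking index
    saturation at high wax loads.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 2:
        raise ValueError("predicted and observed must have equal length >= 2")
    residuals = observed - predicted
    rmse = float(np.sqrt(np.mean(residuals**2)))
    if np.std(predicted) == 0 or np.std(observed) == 0:
        r2 = float("nan")
    else:
        r2 = float(stats.pearsonr(observed, predicted)[0] ** 2)
    return {"rmse": rmse, "r2": r2, "residuals": residuals}
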