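"""Empirical-line calibration of aerial digital counts to reflectance.

Ground calibration tarps of known reflectance (nominally 8 %, 16 %, 32 % and
48 %) are imaged together with the plots.  Per spectral band, an ordinary
least-squares line maps the tarps' digital counts (DC, the independent
variable) to the reflectance measured on the tarps with a ground
spectroradiometer (the response).  Applying the per-band lines to plot-level
DC tables yields canopy reflectance for downstream index math.

The fit/apply pair is exposed as a scikit-learn style transformer,
:class:`EmpiricalLineCalibrator`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TarpObservation",
    "EmpiricalLineModel",
    "EmpiricalLineCalibrator",
    "fit_empirical_line",
    "apply_empirical_line",
    "NOMINAL_TARP_LEVELS",
]

#: Nominal reflectance of the standard four-tarp calibration set.
NOMINAL_TARP_LEVELS = (0.08, 0.16, 0.32, 0.48)


@dataclass(frozen=True)
class TarpObservation:
    """One calibration tarp: nominal level, measured reflectance and DC per band."""

    tarp_id: str
    nominal_reflectance: float
    wavelengths_nm: np.ndarray
    reference_reflectance: np.ndarray  # ground-spectroradiometer truth, fractions
    digital_counts: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ref = np.asarray(self.reference_reflectance, dtype=float)
        dc = np.asarray(self.digital_counts, dtype=float)
        if not (wl.shape == ref.shape == dc.shape):
            raise ValueError("per-band arrays must share one length")
        if not np.all(np.isfinite(dc)):
            raise ValueError("digital counts must be finite")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reference_reflectance", ref)
        object.__setattr__(self, "digital_counts", dc)


@dataclass(frozen=True)
class EmpiricalLineModel:
    """Per-band line reflectance = intercept + slope * DC, with fit R^2."""

    wavelengths_nm: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    r2: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        s = np.asarray(self.slope, dtype=float)
        b = np.asarray(self.intercept, dtype=float)
        if not (wl.shape == s.shape == b.shape):
            raise ValueError("per-band arrays must share one length")
        if not np.all(np.isfinite(s)):
            raise ValueError("slopes must be finite")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "slope", s)
        object.__setattr__(self, "intercept", b)
        if self.r2 is not None:
            object.__setattr__(self, "r2", np.asarray(self.r2, dtype=float))


def fit_empirical_line(tarps) -> EmpiricalLineModel:
    """Per-band OLS of measured tarp reflectance on digital counts.

    With exactly two tarps the fitted line interpolates both points exactly.
    A band where all tarps share one DC is degenerate and raises, naming the
    band.
    """
    tarps = list(tarps)
    if len(tarps) < 2:
        raise ValueError("need at least 2 tarps")
    wl = tarps[0].wavelengths_nm
    for t in tarps[1:]:
        if not np.array_equal(t.wavelengths_nm, wl):
            raise ValueError("tarps must share one band grid")
    dc = np.vstack([t.digital_counts for t in tarps])  # tarps x bands
    ref = np.vstack([t.reference_reflectance for t in tarps])
    dc_mean = dc.mean(axis=0)
    sxx = np.sum((dc - dc_mean) ** 2, axis=0)
    degenerate = np.flatnonzero(sxx == 0)
    if degenerate.size:
        raise ValueError(
            f"identical digital counts across tarps at band(s) "
            f"{wl[degenerate][:5].tolist()} nm"
        )
    ref_mean = ref.mean(axis=0)
    slope = np.sum((dc - dc_mean) * (ref - ref_mean), axis=0) / sxx
    intercept = ref_mean - slope * dc_mean
    fitted = intercept + slope * dc
    ss_res = np.sum((ref - fitted) ** 2, axis=0)
    ss_tot = np.sum((ref - ref_mean) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    return EmpiricalLineModel(wl, slope, intercept, r2)


def apply_empirical_line(dc_table: pd.DataFrame, model: EmpiricalLineModel) -> pd.DataFrame:
    """Convert a plots x bands DC table to reflectance via the fitted lines.

    Columns must be the band wavelengths (nm) of the model.  Values outside
    [0, 1.2] are left as computed but flagged with a warning.
    """
    cols = np.asarray([float(c) for c in dc_table.columns])
    if cols.shape != model.wavelengths_nm.shape or not np.allclose(
        cols, model.wavelengths_nm
    ):
        raise ValueError("DC table bands do not match the empirical-line model bands")
    if np.any(model.slope == 0):
        warnings.warn("zero-slope band(s): output constant at the intercept there")
    refl = model.intercept + model.slope * dc_table.to_numpy(dtype=float)
    out_of_range = (refl < 0) | (refl > 1.2)
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} calibrated reflectance value(s) outside [0, 1.2]"
        )
    return pd.DataFrame(refl, index=dc_table.index, columns=dc_table.columns)


class EmpiricalLineCalibrator(TransformerMixin, BaseEstimator):
    """Scikit-learn style wrapper: fit on tarps, transform DC arrays.

    ``fit(X, y)`` takes tarp digital counts X (tarps x bands) and measured
    tarp reflectance y (tarps x bands); ``transform(X)`` maps any
    (rows x bands) DC array to reflectance.
    """

    def __init__(self, wavelengths_nm=None):
        self.wavelengths_nm = wavelengths_nm

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape or X.shape[0] < 2:
            raise ValueError("need >= 2 tarps with matching DC/reflectance shapes")
        wl = (
            np.asarray(self.wavelengths_nm, dtype=float)
            if self.wavelengths_nm is not None
            else np.arange(X.shape[1], dtype=float)
        )
        tarps = [
            TarpObservation(f"tarp-{i}", float(np.mean(y[i])), wl, y[i], X[i])
            for i in range(X.shape[0])
        ]
        self.model_ = fit_empirical_line(tarps)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return self.model_.intercept + self.model_.slope * X
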