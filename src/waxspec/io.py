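"""CSV / JSON readers and writers for the package's standard tables.

Formats
-------
* Spectra (wide CSV): first column ``wavelength_nm``, one column per sample,
  UTF-8, dot decimal.  Reflectance is stored as unitless fractions; on read,
  a table containing any value > 1.5 is auto-interpreted as percent and
  divided by 100 (override with ``scale=``).
* Trial (long CSV): columns ``genotype,rep,trait,value``.
* Tarps (long CSV): columns ``tarp_id,band_nm,dc,ref_reflectance``.
* Calibrations (JSON): ``{"name": "EWI-1", "a": ..., "B": ..., ...}``;
  band-linear wax models analogously with a ``"coef": {"424": ...}`` map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .aerial import TarpObservation
from .prediction import EWMModel, IndexCalibration
from .quantgen import TrialData
from .signature import SpectralSignature

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_trial_csv",
    "write_trial_csv",
    "read_tarps_csv",
    "read_calibration_json",
    "write_calibration_json",
    "read_ewm_json",
    "write_ewm_json",
]

PERCENT_THRESHOLD = 1.5  # values above this are assumed to be percent


def read_spectra_csv(path, scale: str = "auto") -> dict[str, SpectralSignature]:
    """Read a wide spectra CSV into {sample_name: SpectralSignature}.

    ``scale`` is one of 'auto' (divide by 100 when any value > 1.5),
    'fraction' (take as-is) or 'percent' (always divide by 100).
    """
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError(
            f"first column must be 'wavelength_nm', got '{df.columns[0]}'"
        )
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    out: dict[str, SpectralSignature] = {}
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        if scale == "percent" or (scale == "auto" and np.nanmax(vals) > PERCENT_THRESHOLD):
            vals = vals / 100.0
        elif scale not in ("auto", "fraction", "percent"):
            raise ValueError("scale must be 'auto', 'fraction' or 'percent'")
        out[col] = SpectralSignature(wl, vals, {"sample_id": col})
    return out


def write_spectra_csv(signatures: dict[str, SpectralSignature], path) -> None:
    """Write {name: signature} to a wide CSV (fractions, shared grid)."""
    items = list(signatures.items())
    if not items:
        raise ValueError("nothing to write")
    grid = items[0][1].wavelengths_nm
    data = {"wavelength_nm": grid}
    for name, sig in items:
        if not np.array_equal(sig.wavelengths_nm, grid):
            raise ValueError(f"signature '{name}' is on a different grid")
        data[name] = sig.reflectance
    pd.DataFrame(data).to_csv(path, index=False)


def read_trial_csv(path) -> TrialData:
    return TrialData(pd.read_csv(path))


def write_trial_csv(trial: TrialData, path) -> None:
    trial.records.to_csv(path, index=False)


def read_tarps_csv(path) -> list[TarpObservation]:
    """Read tarp calibration rows (tarp_id,band_nm,dc,ref_reflectance)."""
    df = pd.read_csv(path)
    required = {"tarp_id", "band_nm", "dc", "ref_reflectance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tarp table missing column(s) {sorted(missing)}")
    tarps = []
    for tarp_id, sub in df.groupby("tarp_id", sort=True):
        sub = sub.sort_values("band_nm")
        tarps.append(
            TarpObservation(
                str(tarp_id),
                float(sub["ref_reflectance"].mean()),
                sub["band_nm"].to_numpy(dtype=float),
                sub["ref_reflectance"].to_numpy(dtype=float),
                sub["dc"].to_numpy(dtype=float),
            )
        )
    return tarps


def read_calibration_json(path) -> IndexCalibration:
    d = json.loads(Path(path).read_text())
    return IndexCalibration(
        d["name"],
        float(d["a"]),
        float(d["B"]),
        r2=d.get("r2"),
        rmse_mg_dm2=d.get("rmse"),
        ci95=tuple(d["ci95"]) if d.get("ci95") else None,
        source=d.get("source", "user-fit"),
    )


def write_calibration_json(calib: IndexCalibration, path) -> None:
    d = {"name": calib.index_name, "a": calib.a, "B": calib.B}
    if calib.r2 is not None:
        d["r2"] = calib.r2
    if calib.rmse_mg_dm2 is not None:
        d["rmse"] = calib.rmse_mg_dm2
    if calib.ci95 is not None:
        d["ci95"] = list(calib.ci95)
    Path(path).write_text(json.dumps(d, indent=2))


def read_ewm_json(path) -> EWMModel:
    d = json.loads(Path(path).read_text())
    coefs = {int(k): float(v) for k, v in d["coef"].items()}
    return EWMModel(d["name"], float(d["intercept"]), coefs, rmse=d.get("rmse"), r2=d.get("r2"))


def write_ewm_json(model: EWMModel, path) -> None:
    d = {
        "name": model.name,
        "intercept": model.intercept,
        "coef": {str(k): v for k, v in model.coefficients.items()},
    }
    if model.rmse is not None:
        d["rmse"] = model.rmse
    if model.r2 is not None:
        d["r2"] = model.r2
    Path(path).write_text(json.dumps(d, indent=2))
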