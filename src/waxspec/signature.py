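"""Reflectance signatures and the preprocessing applied before any index math.

A :class:`SpectralSignature` is a wavelength-indexed vector of unitless
reflectance fractions (percent / 100).  Field and leaf spectrometers deliver
raw digital counts plus white/dark reference scans; the functions here perform
the standard two-point calibration, clip to the 400-900 nm working range,
coarsen a ~1 nm native grid to 3 nm by windowed averaging, and average the
repeated readings taken on each leaf or plot.  Broad visible/NIR regions
(violet ... NIR) are summarised as range means for the broad-band indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SpectralSignature",
    "ReplicateSet",
    "BroadBands",
    "BROAD_BAND_RANGES",
    "CalibrationError",
    "BandNotFoundError",
    "GridMismatchError",
    "calibrate_raw",
    "clip_range",
    "resample_3nm",
    "average_replicates",
    "band_at",
    "broad_bands",
]


class CalibrationError(ValueError):
    """White/dark reference pair is degenerate at one or more bands."""


class BandNotFoundError(KeyError):
    """No channel within tolerance of the requested wavelength."""


class GridMismatchError(ValueError):
    """Signatures do not share an identical wavelength grid."""


@dataclass(frozen=True)
class SpectralSignature:
    """A single reflectance spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array-like of float
        Band centers in nanometers, strictly increasing.
    reflectance : array-like of float
        Unitless reflectance fractions, same length, finite and >= 0.
        Values above 1 are rejected unless ``meta['calibration_noise']`` is
        truthy (empirical-line output can slightly overshoot 100 %).
    meta : mapping, optional
        Sample identifier and acquisition tags, e.g. ``side`` in
        {'adaxial', 'abaxial', 'canopy', 'aerial'}.
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", refl)
        if wl.ndim != 1 or refl.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if wl.shape != refl.shape:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {refl.size} reflectance values"
            )
        if wl.size == 0:
            raise ValueError("empty signature")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(refl)):
            raise ValueError("reflectance must be finite")
        if np.any(refl < 0):
            raise ValueError("reflectance must be non-negative")
        if np.any(refl > 1) and not self.meta.get("calibration_noise"):
            raise ValueError(
                "reflectance > 1 requires meta['calibration_noise']=True "
                "(values look like percent? divide by 100)"
            )

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def with_values(self, reflectance: np.ndarray, **meta_updates) -> "SpectralSignature":
        meta = {**self.meta, **meta_updates}
        return SpectralSignature(self.wavelengths_nm, reflectance, meta)


@dataclass(frozen=True)
class ReplicateSet:
    """Repeated readings of one plot/sample sharing a single wavelength grid."""

    signatures: tuple
    sample_id: str = ""

    def __post_init__(self) -> None:
        sigs = tuple(self.signatures)
        object.__setattr__(self, "signatures", sigs)
        if not sigs:
            raise ValueError("ReplicateSet must be non-empty")
        grid = sigs[0].wavelengths_nm
        for s in sigs[1:]:
            if s.wavelengths_nm.shape != grid.shape or not np.array_equal(
                s.wavelengths_nm, grid
            ):
                raise GridMismatchError("replicates do not share one wavelength grid")


#: Closed wavelength ranges (nm) defining each broad visible/NIR region.
#: Red (622-748) deliberately overlaps red-edge (691-730), as tabulated in
#: the source convention this package follows.
BROAD_BAND_RANGES: Mapping[str, tuple[float, float]] = {
    "violet": (400.0, 451.0),
    "blue": (454.0, 496.0),
    "green": (499.0, 517.0),
    "yellow": (574.0, 589.0),
    "orange": (592.0, 619.0),
    "red": (622.0, 748.0),
    "red_edge": (691.0, 730.0),
    "nir": (751.0, 997.0),
}


@dataclass(frozen=True)
class BroadBands:
    """Mean reflectance per named visible/NIR region; None when the grid has
    no channel inside a region."""

    violet: float | None = None
    blue: float | None = None
    green: float | None = None
    yellow: float | None = None
    orange: float | None = None
    red: float | None = None
    red_edge: float | None = None
    nir: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in BROAD_BAND_RANGES}


def calibrate_raw(
    raw: Sequence[float],
    white: Sequence[float],
    dark: Sequence[float],
    wavelengths: Sequence[float],
    meta: dict | None = None,
) -> SpectralSignature:
    """Two-point radiometric calibration against white and dark references.

    reflectance = (raw - dark) / (white - dark) per band, so the white
    reference maps to 1 and the dark panel to 0.
    """
    raw = np.asarray(raw, dtype=float)
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if not (raw.shape == white.shape == dark.shape == wl.shape):
        raise ValueError("raw, white, dark and wavelengths must have equal length")
    span = white - dark
    bad = np.flatnonzero(span <= 0)
    if bad.size:
        raise CalibrationError(
            f"white <= dark at band(s) {wl[bad][:5].tolist()} nm: calibration degenerate"
        )
    refl = (raw - dark) / span
    m = dict(meta or {})
    m.setdefault("calibration_noise", True)  # raw scans can exceed the white scan
    refl = np.clip(refl, 0.0, None)
    return SpectralSignature(wl, refl, m)


def clip_range(
    sig: SpectralSignature, lo: float = 400.0, hi: float = 900.0
) -> SpectralSignature:
    """Retain only bands with lo <= wavelength <= hi (order preserved)."""
    if not lo < hi:
        raise ValueError(f"lo must be < hi, got [{lo}, {hi}]")
    mask = (sig.wavelengths_nm >= lo) & (sig.wavelengths_nm <= hi)
    if not mask.any():
        raise ValueError(f"no bands in range [{lo}, {hi}] nm")
    return SpectralSignature(
        sig.wavelengths_nm[mask], sig.reflectance[mask], dict(sig.meta)
    )


def resample_3nm(sig: SpectralSignature, window_nm: float = 3.0) -> SpectralSignature:
    """Coarsen resolution by averaging consecutive channels in 3-channel windows.

    Non-overlapping windows are anchored at the first retained wavelength;
    each output band is the mean reflectance of its window and sits at the
    window-center wavelength.  A trailing partial window is averaged as-is.
    """
    n = len(sig)
    if n < 3:
        raise ValueError("resampling needs at least 3 channels")
    k = 3  # channels per window; the instrument grid is ~1 nm so 3 channels ~ window_nm
    n_out = int(np.ceil(n / k))
    wl_out = np.empty(n_out)
    refl_out = np.empty(n_out)
    for i in range(n_out):
        sl = slice(i * k, min((i + 1) * k, n))
        wl_out[i] = sig.wavelengths_nm[sl].mean()
        refl_out[i] = sig.reflectance[sl].mean()
    return SpectralSignature(wl_out, refl_out, dict(sig.meta))


def average_replicates(reps: ReplicateSet) -> SpectralSignature:
    """Per-band arithmetic mean across the repeated readings of one sample."""
    stack = np.vstack([s.reflectance for s in reps.signatures])
    meta = dict(reps.signatures[0].meta)
    meta["n_averaged"] = len(reps.signatures)
    if reps.sample_id:
        meta.setdefault("sample_id", reps.sample_id)
    return SpectralSignature(reps.signatures[0].wavelengths_nm, stack.mean(axis=0), meta)


def band_at(sig: SpectralSignature, target: float, tol: float = 2.0) -> float:
    """Reflectance of the channel nearest ``target`` nm.

    Ties break to the lower wavelength.  Raises BandNotFoundError when the
    nearest channel is farther than ``tol``.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    dist = np.abs(sig.wavelengths_nm - target)
    i = int(np.argmin(dist))  # argmin returns first (lower-wavelength) minimum
    if dist[i] > tol:
        raise BandNotFoundError(
            f"no channel within {tol} nm of {target} nm "
            f"(nearest available: {sig.wavelengths_nm[i]} nm)"
        )
    return float(sig.reflectance[i])


def broad_bands(sig: SpectralSignature) -> BroadBands:
    """Mean reflectance over each named region, intersected with the grid.

    Regions with no channel on the grid come back as None rather than raising,
    so a 400-900 nm clipped spectrum still yields a NIR mean (over 751-900).
    """
    values: dict[str, float | None] = {}
    for name, (lo, hi) in BROAD_BAND_RANGES.items():
        mask = (sig.wavelengths_nm >= lo) & (sig.wavelengths_nm <= hi)
        values[name] = float(sig.reflectance[mask].mean()) if mask.any() else None
    return BroadBands(**values)
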