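"""Synthetic leaf spectra, replicated trials and aerial tarp scenes.

The generator encodes the empirically observed linear response of wheat-leaf
reflectance to epicuticular wax load: per mg/dm^2 of wax, reflectance rises
by ~0.82 % over 424-450 nm and ~0.79 % over 544-575 nm, falls by ~0.77-0.8 %
over 713-720 nm (strongest at 717 nm), and rises by ~1.5 % over 756-825 nm;
wavelengths outside these windows are unaffected.  Segment edges carry 3-nm
cosine tapers so the injected effect is spectrally smooth.

A simulated trial draws genotype wax effects ~ N(0, sigma_g^2) around a
population mean and plot errors ~ N(0, sigma_e^2) — the variance structure of
a balanced two-replicate field trial — then renders one spectrum per plot by
adding the wax effect to a parametric green-leaf baseline plus band-wise
Gaussian noise.  Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aerial import NOMINAL_TARP_LEVELS, TarpObservation
from .quantgen import TrialData
from .signature import SpectralSignature

__all__ = [
    "WaxEffectProfile",
    "SimulationConfig",
    "SimulatedTrial",
    "default_wax_profile",
    "default_grid",
    "baseline_leaf_spectrum",
    "apply_wax_effect",
    "simulate_trial",
    "simulate_leaf_panel",
    "simulate_tarp_scene",
]


def default_grid() -> np.ndarray:
    """The 200-band 3-nm grid over 400-997 nm used throughout."""
    return np.arange(400.0, 998.0, 3.0)


@dataclass(frozen=True)
class WaxEffectProfile:
    """Additive reflectance change per mg/dm^2 of wax, as a function of nm.

    Defined by anchor points (wavelength, slope); between anchors the slope
    is cosine-interpolated, outside the overall support it is exactly zero.
    """

    anchors_nm: np.ndarray
    anchors_value: np.ndarray

    def __post_init__(self) -> None:
        nm = np.asarray(self.anchors_nm, dtype=float)
        val = np.asarray(self.anchors_value, dtype=float)
        if nm.shape != val.shape or nm.size < 2:
            raise ValueError("need >= 2 anchor points of equal length")
        if not np.all(np.diff(nm) > 0):
            raise ValueError("anchor wavelengths must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValueError("anchor values must be finite")
        object.__setattr__(self, "anchors_nm", nm)
        object.__setattr__(self, "anchors_value", val)

    def __call__(self, wavelengths_nm) -> np.ndarray:
        wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        out = np.zeros_like(wl)
        inside = (wl >= self.anchors_nm[0]) & (wl <= self.anchors_nm[-1])
        if inside.any():
            idx = np.searchsorted(self.anchors_nm, wl[inside], side="right") - 1
            idx = np.clip(idx, 0, self.anchors_nm.size - 2)
            x0 = self.anchors_nm[idx]
            x1 = self.anchors_nm[idx + 1]
            v0 = self.anchors_value[idx]
            v1 = self.anchors_value[idx + 1]
            frac = np.where(x1 > x0, (wl[inside] - x0) / (x1 - x0), 0.0)
            smooth = 0.5 * (1.0 - np.cos(np.pi * frac))  # cosine taper
            out[inside] = v0 + (v1 - v0) * smooth
        return out if np.ndim(wavelengths_nm) else float(out[0])


def default_wax_profile() -> WaxEffectProfile:
    """Wax-effect slopes with 3-nm cosine tapers at every segment edge.

    Plateau values: +0.0082 (424-450 nm), +0.0079 (544-575 nm), -0.0077 over
    713-720 nm deepening to -0.008 at the 717 nm peak, +0.015 (756-825 nm);
    zero between 575 and 713 nm and above 825 nm (no measured response
    there).
    """
    anchors = [
        (421, 0.0), (424, 0.0082), (450, 0.0082), (453, 0.0),
        (541, 0.0), (544, 0.0079), (575, 0.0079), (578, 0.0),
        (710, 0.0), (713, -0.0077), (717, -0.008), (720, -0.0077), (723, 0.0),
        (753, 0.0), (756, 0.015), (825, 0.015), (828, 0.0),
    ]
    nm, val = zip(*anchors)
    return WaxEffectProfile(np.array(nm, dtype=float), np.array(val, dtype=float))


@dataclass(frozen=True)
class SimulationConfig:
    """Trial-simulation parameters; the defaults mirror a two-replicate wheat
    trial with EW mean ~1.7 mg/dm^2 and genetic/error variances ~0.014.

    ``spectral_noise_sd`` is the per-reading band noise; each plot spectrum is
    the average of ``n_readings`` readings (the standard field protocol takes
    ten per plot), so its effective noise is sd / sqrt(n_readings).
    """

    g: int = 50
    r: int = 2
    sigma2_g: float = 0.014
    sigma2_e: float = 0.014
    ew_mean: float = 1.72
    spectral_noise_sd: float = 0.005
    n_readings: int = 10
    grid: np.ndarray = field(default_factory=default_grid)
    seed: int = 0
    ground_cover: float = 1.0  # canopy spectra: leaf spectrum scaled by cover in (0.5, 1]

    def __post_init__(self) -> None:
        if self.g < 2 or self.r < 1:
            raise ValueError("need g >= 2 genotypes and r >= 1 replicates")
        if self.sigma2_g < 0 or self.sigma2_e < 0 or self.spectral_noise_sd < 0:
            raise ValueError("variances and noise sd must be >= 0")
        if self.n_readings < 1:
            raise ValueError("n_readings must be >= 1")
        if not 0.5 < self.ground_cover <= 1.0:
            raise ValueError("ground_cover must be in (0.5, 1]")
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))


def baseline_leaf_spectrum(grid=None, nir_plateau: float = 0.45, meta=None) -> SpectralSignature:
    """Parametric green-leaf reflectance: pigment troughs, green bump, logistic
    red edge centered near 715 nm, NIR plateau.

    Smooth, strictly positive, values in (0, 0.6), monotone through the red
    edge (700-740 nm).  Deterministic for a given grid and parameters.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.min() < 400 or grid.max() > 1000:
        raise ValueError("grid must lie within 400-1000 nm")
    vis = 0.05 + 0.07 * np.exp(-(((grid - 550.0) / 35.0) ** 2))
    edge = 1.0 / (1.0 + np.exp(-(grid - 715.0) / 9.0))
    refl = vis * (1.0 - edge) + nir_plateau * edge
    return SpectralSignature(grid, refl, dict(meta or {}))


def apply_wax_effect(
    sig: SpectralSignature, ew: float, profile: WaxEffectProfile | None = None
) -> SpectralSignature:
    """Shift a spectrum by ew * profile(lambda), floored at zero reflectance."""
    if ew < 0:
        raise ValueError("wax load must be >= 0")
    profile = profile or default_wax_profile()
    shifted = np.clip(sig.reflectance + ew * profile(sig.wavelengths_nm), 0.0, None)
    return sig.with_values(shifted, ew_mg_dm2=float(ew))


@dataclass(frozen=True)
class SimulatedTrial:
    """A simulated balanced trial: trait records, per-plot spectra, truth."""

    trial: TrialData
    spectra: pd.DataFrame  # plots x bands, reflectance fractions
    ew: pd.Series  # plot id -> wax load used to render its spectrum
    config: SimulationConfig
    genotype_effects: pd.Series


def simulate_trial(config: SimulationConfig | None = None, **overrides) -> SimulatedTrial:
    """Simulate a balanced genotype x replicate wax trial with spectra.

    Genotype effects ~ N(0, sigma_g^2) around ``ew_mean``; each plot adds
    error ~ N(0, sigma_e^2); the plot spectrum is the leaf baseline (scaled
    by ground cover) plus the wax effect plus band-wise Gaussian noise.
    Fully deterministic under ``config.seed``.
    """
    config = config or SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    base = baseline_leaf_spectrum(config.grid).reflectance * config.ground_cover
    profile = default_wax_profile()
    effect = profile(config.grid)

    geno_eff = rng.normal(0.0, np.sqrt(config.sigma2_g), size=config.g)
    records = []
    spectra = []
    ew_values = {}
    for gi in range(config.g):
        for ri in range(config.r):
            err = rng.normal(0.0, np.sqrt(config.sigma2_e))
            ew = max(config.ew_mean + geno_eff[gi] + err, 0.0)
            plot_id = f"G{gi + 1:03d}_R{ri + 1}"
            records.append((f"G{gi + 1:03d}", ri + 1, "EW", ew))
            noise_sd = config.spectral_noise_sd / np.sqrt(config.n_readings)
            noise = rng.normal(0.0, noise_sd, size=config.grid.size)
            spectra.append(np.clip(base + ew * effect + noise, 0.0, None))
            ew_values[plot_id] = ew
    trial = TrialData(pd.DataFrame(records, columns=["genotype", "rep", "trait", "value"]))
    panel = pd.DataFrame(np.vstack(spectra), index=list(ew_values), columns=config.grid)
    return SimulatedTrial(
        trial=trial,
        spectra=panel,
        ew=pd.Series(ew_values, name="EW"),
        config=config,
        genotype_effects=pd.Series(geno_eff, index=[f"G{i + 1:03d}" for i in range(config.g)]),
    )


def simulate_leaf_panel(
    n: int = 100,
    ew_range: tuple = (0.5, 4.0),
    spectral_noise_sd: float = 0.005,
    n_readings: int = 10,
    grid=None,
    seed: int = 0,
):
    """Simulate a single-leaf calibration panel spanning a wide wax range.

    Each leaf draws its wax load uniformly from ``ew_range`` (mg/dm^2) and
    its spectrum is the average of ``n_readings`` noisy readings of the
    baseline-plus-wax-effect spectrum.  This emulates the paired
    (spectrum, chemically measured wax) data used to calibrate indices,
    where the sampled material deliberately spans low to high wax loads.

    Returns ``(spectra, ew)``: a leaves x bands DataFrame and the matching
    wax Series.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    base = baseline_leaf_spectrum(grid).reflectance
    effect = default_wax_profile()(grid)
    ew = rng.uniform(ew_range[0], ew_range[1], size=n)
    noise_sd = spectral_noise_sd / np.sqrt(n_readings)
    panel = np.clip(
        base + np.outer(ew, effect) + rng.normal(0.0, noise_sd, (n, grid.size)),
        0.0,
        None,
    )
    idx = [f"leaf-{i + 1:03d}" for i in range(n)]
    return (
        pd.DataFrame(panel, index=idx, columns=grid),
        pd.Series(ew, index=idx, name="EW"),
    )


def simulate_tarp_scene(
    slope,
    intercept,
    wavelengths_nm=None,
    tarp_levels=NOMINAL_TARP_LEVELS,
    noise_sd_dc: float = 0.0,
    n_plots: int = 12,
    seed: int = 0,
):
    """Synthesise a tarp-calibration scene from known per-band lines.

    DCs are generated by inverting reflectance = intercept + slope * DC at
    the tarp levels and at random plot reflectances, optionally adding
    Gaussian DC noise.  Returns ``(tarps, dc_table, truth_table)`` where the
    truth table holds the noise-free plot reflectance for round-trip tests.
    """
    slope = np.atleast_1d(np.asarray(slope, dtype=float))
    intercept = np.broadcast_to(
        np.atleast_1d(np.asarray(intercept, dtype=float)), slope.shape
    ).astype(float)
    if np.any(slope == 0):
        raise ValueError("zero-slope band(s): scene not invertible")
    wl = (
        np.asarray(wavelengths_nm, dtype=float)
        if wavelengths_nm is not None
        else np.arange(slope.size, dtype=float)
    )
    rng = np.random.default_rng(seed)
    tarps = []
    for level in tarp_levels:
        ref = np.full(slope.shape, float(level))
        dc = (ref - intercept) / slope
        dc = dc + rng.normal(0.0, noise_sd_dc, size=dc.shape)
        tarps.append(TarpObservation(f"tarp-{int(level * 100)}pct", float(level), wl, ref, dc))
    truth = rng.uniform(0.05, 0.55, size=(n_plots, slope.size))
    dc_plots = (truth - intercept) / slope
    dc_plots = dc_plots + rng.normal(0.0, noise_sd_dc, size=dc_plots.shape)
    idx = [f"plot-{i + 1:02d}" for i in range(n_plots)]
    return (
        tarps,
        pd.DataFrame(dc_plots, index=idx, columns=wl),
        pd.DataFrame(truth, index=idx, columns=wl),
    )
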