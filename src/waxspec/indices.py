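"""Spectral vegetation indices and the epicuticular-wax (EWI) index family.

Three registries are exposed:

* ``NARROW_INDICES`` — 15 literature narrow-band indices (WI, PRI, CARI,
  PSSR, ARI, SIPI, ...) each citing exact wavelengths such as rho_900.
* ``BROAD_INDICES`` — 14 literature indices over the named region means
  (NDVI, SR, RDVI, ...).
* ``EWI_INDICES`` — the 14 wax indices EWI-1..EWI-14: EWI-1..4 combine the
  blue/red/NIR region means, EWI-5..14 combine one to three narrow bands in
  the chlorophyll-absorption / red-edge / NIR window (622-832 nm).

All formulas are transcribed literally from their tabulated definitions,
including forms that look unconventional (e.g. NDWI as a plain band ratio,
RGRI as a difference); fidelity to the printed definition wins over
index-naming conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy import stats

from .signature import BandNotFoundError, BroadBands, SpectralSignature, band_at

__all__ = [
    "IndexDefinition",
    "IndexResult",
    "NARROW_INDICES",
    "BROAD_INDICES",
    "EWI_INDICES",
    "compute_narrow_indices",
    "compute_broad_indices",
    "compute_ewi",
    "correlate_indices",
]


@dataclass(frozen=True)
class IndexDefinition:
    """One spectral index: a named arithmetic combination of bands/regions."""

    name: str
    family: str  # literature-narrow | literature-broad | ewi
    required_bands: tuple  # nm values (float) and/or region names (str)
    formula: str  # human-readable expression, as printed
    fn: Callable[[Mapping], float]

    def evaluate(self, bands: Mapping) -> float:
        return float(self.fn(bands))


@dataclass
class IndexResult:
    """Computed index values plus provenance and reasons for missing ones."""

    values: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)  # name -> {band: value used}
    missing: dict = field(default_factory=dict)  # name -> reason string

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values)


def _d(name, family, bands, formula, fn):
    return IndexDefinition(name, family, tuple(bands), formula, fn)


NARROW_INDICES: dict[str, IndexDefinition] = {
    d.name: d
    for d in [
        _d("WI", "literature-narrow", (900, 970), "p900 / p970", lambda b: b[900] / b[970]),
        _d("PRI-1", "literature-narrow", (531, 570), "(p531 - p570) / (p531 + p570)",
           lambda b: (b[531] - b[570]) / (b[531] + b[570])),
        _d("PRI-2", "literature-narrow", (570, 539), "(p570 - p539) / (p570 + p539)",
           lambda b: (b[570] - b[539]) / (b[570] + b[539])),
        _d("RGI", "literature-narrow", (690, 550), "p690 / p550", lambda b: b[690] / b[550]),
        # printed as the plain ratio p970/p900, not a normalized difference
        _d("NDWI", "literature-narrow", (970, 900), "p970 / p900", lambda b: b[970] / b[900]),
        _d("CARI-1", "literature-narrow", (510, 550), "p510 / p550", lambda b: b[510] / b[550]),
        _d("CARI-2", "literature-narrow", (510, 700), "(1/p510) / (1/p700)",
           lambda b: (1.0 / b[510]) / (1.0 / b[700])),
        _d("PSRI", "literature-narrow", (680, 500, 750), "(p680 - p500) / p750",
           lambda b: (b[680] - b[500]) / b[750]),
        _d("NPCI", "literature-narrow", (680, 430), "(p680 - p430) / (p680 + p430)",
           lambda b: (b[680] - b[430]) / (b[680] + b[430])),
        _d("PSSR-b", "literature-narrow", (800, 650), "p800 / p650", lambda b: b[800] / b[650]),
        _d("PSSR-a", "literature-narrow", (800, 675), "p800 / p675", lambda b: b[800] / b[675]),
        _d("ARI-1", "literature-narrow", (550, 700), "(1/p550) / (1/p700)",
           lambda b: (1.0 / b[550]) / (1.0 / b[700])),
        _d("ARI-2", "literature-narrow", (800, 550, 700), "p800 * (1/p550) / (1/p700)",
           lambda b: b[800] * (1.0 / b[550]) / (1.0 / b[700])),
        _d("SIPI-1", "literature-narrow", (800, 450, 650), "(p800 - p450) / (p800 + p650)",
           lambda b: (b[800] - b[450]) / (b[800] + b[650])),
        _d("SIPI-2", "literature-narrow", (800, 440, 680), "(p800 - p440) / (p800 + p680)",
           lambda b: (b[800] - b[440]) / (b[800] + b[680])),
    ]
}

BROAD_INDICES: dict[str, IndexDefinition] = {
    d.name: d
    for d in [
        _d("NDVI", "literature-broad", ("nir", "red"), "(NIR - Red) / (NIR + Red)",
           lambda b: (b["nir"] - b["red"]) / (b["nir"] + b["red"])),
        _d("SR", "literature-broad", ("nir", "red"), "NIR / Red", lambda b: b["nir"] / b["red"]),
        _d("NDVI-green", "literature-broad", ("nir", "green"),
           "(NIR - Green) / (NIR + Green)",
           lambda b: (b["nir"] - b["green"]) / (b["nir"] + b["green"])),
        # printed with Red, not NIR, in the numerator
        _d("MSR", "literature-broad", ("nir", "red"), "Red / (NIR/Red + 1)^0.5",
           lambda b: b["red"] / np.sqrt(b["nir"] / b["red"] + 1.0)),
        _d("RDVI", "literature-broad", ("nir", "red"), "(NIR - Red) / (NIR + Red)^0.5",
           lambda b: (b["nir"] - b["red"]) / np.sqrt(b["nir"] + b["red"])),
        # printed as a difference, not a ratio
        _d("RGRI", "literature-broad", ("red", "green"), "Red - Green",
           lambda b: b["red"] - b["green"]),
        _d("RVI", "literature-broad", ("red", "nir"), "Red / NIR", lambda b: b["red"] / b["nir"]),
        _d("DVI", "literature-broad", ("nir", "red"), "NIR - Red", lambda b: b["nir"] - b["red"]),
        _d("SR-NDVI", "literature-broad", ("nir", "red"), "(NIR^2 - Red) / (NIR + Red^2)",
           lambda b: (b["nir"] ** 2 - b["red"]) / (b["nir"] + b["red"] ** 2)),
        _d("NDVI-RE", "literature-broad", ("nir", "red_edge"),
           "(NIR - RedEdge) / (NIR + RedEdge)",
           lambda b: (b["nir"] - b["red_edge"]) / (b["nir"] + b["red_edge"])),
        _d("CI-Red-edge", "literature-broad", ("nir", "red_edge"), "(NIR / RedEdge) - 1",
           lambda b: b["nir"] / b["red_edge"] - 1.0),
        _d("ARI-1", "literature-broad", ("green", "red_edge"), "(1/Green) / (1/RedEdge)",
           lambda b: (1.0 / b["green"]) / (1.0 / b["red_edge"])),
        _d("mARI", "literature-broad", ("green", "red_edge", "nir"),
           "(1/Green) / (1/RedEdge) * NIR",
           lambda b: (1.0 / b["green"]) / (1.0 / b["red_edge"]) * b["nir"]),
        _d("ARI-2", "literature-broad", ("green", "nir"), "Green / NIR",
           lambda b: b["green"] / b["nir"]),
    ]
}

EWI_INDICES: dict[str, IndexDefinition] = {
    d.name: d
    for d in [
        _d("EWI-1", "ewi", ("blue", "red"), "Blue / Red", lambda b: b["blue"] / b["red"]),
        _d("EWI-2", "ewi", ("blue", "nir"), "Blue / NIR", lambda b: b["blue"] / b["nir"]),
        _d("EWI-3", "ewi", ("nir", "red", "blue"), "(NIR - Red) / Blue",
           lambda b: (b["nir"] - b["red"]) / b["blue"]),
        _d("EWI-4", "ewi", ("red", "blue"), "(Red^2 - Blue) / (Red - Blue^2)",
           lambda b: (b["red"] ** 2 - b["blue"]) / (b["red"] - b["blue"] ** 2)),
        _d("EWI-5", "ewi", (676,), "p676", lambda b: b[676]),
        _d("EWI-6", "ewi", (658, 712), "p658 / p712", lambda b: b[658] / b[712]),
        _d("EWI-7", "ewi", (625, 706), "p625 / p706", lambda b: b[625] / b[706]),
        _d("EWI-8", "ewi", (694, 625), "p694 / p625", lambda b: b[694] / b[625]),
        _d("EWI-9", "ewi", (670, 718), "(p670 - p718) / (p670 + p718)",
           lambda b: (b[670] - b[718]) / (b[670] + b[718])),
        # exponent applies to the whole normalized difference
        _d("EWI-10", "ewi", (691, 661), "((p691 - p661) / (p691 + p661))^2",
           lambda b: ((b[691] - b[661]) / (b[691] + b[661])) ** 2),
        _d("EWI-11", "ewi", (661, 694), "(1/p661) - (1/p694)",
           lambda b: 1.0 / b[661] - 1.0 / b[694]),
        _d("EWI-12", "ewi", (622, 718), "(p622 / p718) - 1",
           lambda b: b[622] / b[718] - 1.0),
        _d("EWI-13", "ewi", (625, 736, 832), "p625 * (1/p736 - 1/p832)",
           lambda b: b[625] * (1.0 / b[736] - 1.0 / b[832])),
        _d("EWI-14", "ewi", (625, 736, 832), "(p625 - p736) / p832",
           lambda b: (b[625] - b[736]) / b[832]),
    ]
}


def _resolve_bands(
    definition: IndexDefinition,
    sig: SpectralSignature | None,
    bands: BroadBands | None,
    tol: float,
) -> dict:
    resolved: dict = {}
    for key in definition.required_bands:
        if isinstance(key, str):
            if bands is None:
                raise BandNotFoundError(f"broad region '{key}' needs BroadBands input")
            val = getattr(bands, key)
            if val is None:
                raise BandNotFoundError(f"region '{key}' absent from signature grid")
            resolved[key] = val
        else:
            if sig is None:
                raise BandNotFoundError(f"narrow band {key} nm needs a SpectralSignature")
            resolved[key] = band_at(sig, float(key), tol=tol)
    return resolved


def _compute(
    registry: Mapping[str, IndexDefinition],
    subset: Iterable[str] | None,
    sig: SpectralSignature | None,
    bands: BroadBands | None,
    tol: float = 2.0,
) -> IndexResult:
    names = list(subset) if subset is not None else list(registry)
    unknown = [n for n in names if n not in registry]
    if unknown:
        raise KeyError(f"unknown index name(s): {unknown}")
    result = IndexResult()
    for name in names:
        definition = registry[name]
        try:
            used = _resolve_bands(definition, sig, bands, tol)
            value = definition.evaluate(used)
        except BandNotFoundError as exc:
            result.missing[name] = str(exc)
            continue
        except ZeroDivisionError:
            result.missing[name] = "zero denominator"
            continue
        if not np.isfinite(value):
            result.missing[name] = "non-finite result (zero denominator?)"
            continue
        result.values[name] = value
        result.provenance[name] = used
    return result


def compute_narrow_indices(
    sig: SpectralSignature, subset: Iterable[str] | None = None, tol: float = 2.0
) -> IndexResult:
    """Evaluate the literature narrow-band indices on one signature.

    Indices whose bands cannot be resolved within ``tol`` nm are reported in
    ``result.missing`` with a reason; the rest are still computed.
    """
    return _compute(NARROW_INDICES, subset, sig, None, tol)


def compute_broad_indices(
    bands: BroadBands, subset: Iterable[str] | None = None
) -> IndexResult:
    """Evaluate the literature broad-band indices from region means."""
    return _compute(BROAD_INDICES, subset, None, bands)


def compute_ewi(
    sig: SpectralSignature | None = None,
    bands: BroadBands | None = None,
    subset: Iterable[str] | None = None,
    tol: float = 2.0,
) -> IndexResult:
    """Evaluate the wax indices EWI-1..14.

    EWI-1..4 need broad region means (``bands``); EWI-5..14 need the narrow
    signature (``sig``).  Either input may be omitted if the requested subset
    does not use it.
    """
    return _compute(EWI_INDICES, subset, sig, bands, tol)


def correlate_indices(index_table, trait) -> "pd.DataFrame":
    """Pearson r and two-sided p of each index column against a trait vector.

    Parameters
    ----------
    index_table : DataFrame (samples x indices)
    trait : 1-D array of trait values (e.g. wax load, mg/dm^2), aligned rows.

    Returns
    -------
    DataFrame indexed by index name with columns ``r``, ``p``, ``n`` and
    ``reason`` (non-empty when the correlation is undefined).
    """
    import pandas as pd

    trait = np.asarray(trait, dtype=float)
    rows = []
    for name in index_table.columns:
        x = np.asarray(index_table[name], dtype=float)
        ok = np.isfinite(x) & np.isfinite(trait)
        n = int(ok.sum())
        if n < 3:
            rows.append((name, np.nan, np.nan, n, "fewer than 3 paired observations"))
            continue
        if np.std(x[ok]) == 0 or np.std(trait[ok]) == 0:
            rows.append((name, np.nan, np.nan, n, "zero variance"))
            continue
        r, p = stats.pearsonr(x[ok], trait[ok])
        rows.append((name, float(r), float(p), n, ""))
    return pd.DataFrame(rows, columns=["index", "r", "p", "n", "reason"]).set_index("index")
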