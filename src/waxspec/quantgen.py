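"""Variance components, heritability and indirect-selection statistics.

Replicated-trial tables (genotype x replicate, long form) are analysed with a
balanced two-way method-of-moments ANOVA.  From the expected mean squares,

    sigma_e^2 = MS_error,   sigma_g^2 = (MS_genotype - MS_error) / r,

and broad-sense heritability on an entry-mean basis is

    h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r).

The selection calculus follows the standard quantitative-genetics formulas:
genetic gain GG = h^2 * SDiff, genetic advance GA = K * sigma_p * h^2 (K the
selection differential at a given selection pressure), GAM = 100 * GA / mean,
direct response R = h_x * sigma_x (sigma_x the genotypic SD), correlated
response CR = h_x * r_g * sigma_gy when selecting on a proxy trait, and
relative efficiency RE = CR / R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialData",
    "VarianceComponents",
    "SelectionSummary",
    "variance_components",
    "heritability",
    "genetic_correlation",
    "phenotypic_correlation",
    "genotypic_covariance",
    "selection_metrics",
    "correlated_response",
    "relative_efficiency",
]


@dataclass(frozen=True)
class TrialData:
    """Long-form replicated trial records: genotype, rep, trait, value."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = {"genotype", "rep", "trait", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trial table missing column(s) {sorted(missing)}")
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise ValueError("trait values must be finite")
        if df["genotype"].nunique() < 2:
            raise ValueError("need at least 2 genotypes")
        object.__setattr__(self, "records", df)

    def trait(self, name: str) -> pd.DataFrame:
        sub = self.records[self.records["trait"] == name]
        if sub.empty:
            raise KeyError(f"trait '{name}' not present in trial")
        return sub

    def traits(self) -> list:
        return sorted(self.records["trait"].unique())

    def is_balanced(self, trait: str) -> bool:
        counts = self.trait(trait).groupby("genotype")["rep"].nunique()
        return counts.nunique() == 1

    def genotype_means(self, trait: str) -> pd.Series:
        return self.trait(trait).groupby("genotype")["value"].mean()


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments genetic and error variances from a balanced trial."""

    sigma2_g: float
    sigma2_e: float
    r: int
    grand_mean: float
    cv_percent: float

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")


@dataclass(frozen=True)
class SelectionSummary:
    """Heritability plus direct and (optionally) indirect selection response."""

    h2: float
    sdiff: float
    gg: float
    k: float
    sigma_p: float
    ga: float
    gam_percent: float
    response_R: float
    h_x: float
    sigma_x: float
    r_g: float | None = None
    r_p: float | None = None
    cr: float | None = None
    re: float | None = None


def variance_components(trial: TrialData, trait: str) -> VarianceComponents:
    """Extract sigma_g^2 and sigma_e^2 from a balanced genotype x rep trial.

    Uses the two-way ANOVA (genotype + replicate main effects) expected mean
    squares.  Negative moment estimates are truncated to zero with a warning.
    """
    sub = trial.trait(trait)
    if not trial.is_balanced(trait):
        raise ValueError(
            f"trait '{trait}' is unbalanced; subset to a balanced genotype x rep "
            "table before estimating variance components"
        )
    wide = sub.pivot_table(index="genotype", columns="rep", values="value")
    if wide.isna().any().any():
        raise ValueError("missing genotype x rep cells; design must be complete")
    y = wide.to_numpy(dtype=float)
    g, r = y.shape
    if g < 2 or r < 2:
        raise ValueError("need >= 2 genotypes and >= 2 replicates")
    grand = y.mean()
    gen_means = y.mean(axis=1)
    rep_means = y.mean(axis=0)
    ss_gen = r * np.sum((gen_means - grand) ** 2)
    ss_rep = g * np.sum((rep_means - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_gen - ss_rep
    ms_gen = ss_gen / (g - 1)
    ms_err = ss_err / ((g - 1) * (r - 1))
    sigma2_e = max(ms_err, 0.0)
    sigma2_g = (ms_gen - ms_err) / r
    if sigma2_g < 0:
        warnings.warn(
            f"negative genetic-variance estimate ({sigma2_g:.3g}) truncated to 0"
        )
        sigma2_g = 0.0
    cv = 100.0 * np.sqrt(sigma2_e) / grand if grand != 0 else float("nan")
    return VarianceComponents(
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        r=int(r),
        grand_mean=float(grand),
        cv_percent=float(cv),
    )


def heritability(vc: VarianceComponents | None = None, *, sigma2_g=None, sigma2_e=None, r=None) -> float:
    """Broad-sense heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r).

    Accepts either a :class:`VarianceComponents` or the three raw values.
    """
    if vc is not None:
        sigma2_g, sigma2_e, r = vc.sigma2_g, vc.sigma2_e, vc.r
    denom = sigma2_g + sigma2_e / r
    if denom <= 0:
        raise ValueError("all-zero variances: heritability undefined")
    h2 = sigma2_g / denom
    return float(h2)


def genetic_correlation(cov_xy: float, var_x: float, var_y: float) -> float:
    """Genotypic correlation r_g = COV_XY / sqrt(Var_x * Var_y).

    Moment estimates can exceed |1|; such values are returned with a warning
    (sampling artifact), not clipped.
    """
    if var_x <= 0 or var_y <= 0:
        raise ValueError("variances must be positive")
    r_g = cov_xy / np.sqrt(var_x * var_y)
    if abs(r_g) > 1:
        warnings.warn(f"|r_g| = {abs(r_g):.3f} > 1: sampling artifact of moment estimators")
    return float(r_g)


def phenotypic_correlation(x, y) -> float:
    """Pearson correlation of paired phenotypic observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def genotypic_covariance(trial: TrialData, trait_x: str, trait_y: str) -> float:
    """Plug-in genotypic covariance: covariance of the genotype means."""
    mx = trial.genotype_means(trait_x)
    my = trial.genotype_means(trait_y)
    common = mx.index.intersection(my.index)
    if len(common) < 2:
        raise ValueError("need >= 2 genotypes shared by both traits")
    return float(np.cov(mx[common], my[common], ddof=1)[0, 1])


def selection_metrics(
    values,
    h2: float,
    sigma_g: float,
    sigma_p: float,
    pressure: float = 0.10,
    direction: str = "high",
) -> SelectionSummary:
    """Direct-selection statistics at a given selection pressure.

    The selection differential SDiff (= K) is |mean(selected fraction) -
    population mean|, the selected fraction being the top (``direction
    'high'``) or bottom (``'low'``) ``pressure`` share of the values.  Fills
    GG = h^2 * SDiff, GA = K * sigma_p * h^2, GAM = 100 * GA / mean, and the
    direct response R = sqrt(h^2) * sigma_g.
    """
    values = np.asarray(values, dtype=float)
    if not 0 < pressure <= 1:
        raise ValueError("pressure must be in (0, 1]")
    n = values.size
    n_sel = int(round(n * pressure))
    if n_sel < 1:
        raise ValueError("selected set is empty; increase pressure or sample size")
    order = np.sort(values)
    selected = order[-n_sel:] if direction == "high" else order[:n_sel]
    mean_pop = values.mean()
    sdiff = float(abs(selected.mean() - mean_pop))
    k = sdiff
    gg = h2 * sdiff
    ga = k * sigma_p * h2
    gam = 100.0 * ga / mean_pop if mean_pop != 0 else float("nan")
    h_x = float(np.sqrt(h2))
    response = h_x * sigma_g
    return SelectionSummary(
        h2=float(h2),
        sdiff=sdiff,
        gg=float(gg),
        k=float(k),
        sigma_p=float(sigma_p),
        ga=float(ga),
        gam_percent=float(gam),
        response_R=float(response),
        h_x=h_x,
        sigma_x=float(sigma_g),
    )


def correlated_response(h_x: float, r_g: float, sigma_gy: float) -> float:
    """CR = h_x * r_g * sigma_gy: genetic change in trait Y when selecting on X.

    ``h_x`` is the square root of the proxy's heritability, ``r_g`` the
    genotypic correlation between proxy and target, ``sigma_gy`` the target's
    genotypic standard deviation.  Signed: negative r_g gives negative CR.
    """
    return float(h_x * r_g * sigma_gy)


def relative_efficiency(cr: float, response_R: float) -> float:
    """RE = CR / R: efficiency of indirect relative to direct selection."""
    if response_R == 0:
        raise ValueError("direct response R is zero: relative efficiency undefined")
    return float(cr / response_R)
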