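"""Re-derivation of wax calibrations from paired (spectra, wax) data.

This module owns the statistical machinery used to build the index
calibrations and band-linear wax models from scratch:

* simple-regression calibration lines with leave-one-out cross-validated R^2,
* bootstrap RMSE of inverse prediction (train on a 66 % split, invert on the
  rest, 1000 replicates),
* per-wavelength regression of reflectance on wax load (the "wax effect"
  slope profile),
* NIPALS PLS1 for band selection among hundreds of collinear wavelengths,
* forward/backward stepwise regression driven by partial F-tests with model
  choice by Mallows' Cp.

The fit/predict-shaped procedures are exposed as scikit-learn compatible
estimators (:class:`IndexCalibrator`, :class:`NIPALSPLSRegressor`,
:class:`StepwiseCpRegressor`); the module-level functions are thin wrappers
that add the train/validation splitting conventions used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .prediction import IndexCalibration

__all__ = [
    "FitDiagnostics",
    "SlopeProfile",
    "IndexCalibrator",
    "NIPALSPLSRegressor",
    "StepwiseCpRegressor",
    "fit_index_calibration",
    "loocv_r2",
    "bootstrap_rmse",
    "per_band_slopes",
    "plsr_fit",
    "stepwise_cp",
    "mallows_cp",
]


@dataclass
class FitDiagnostics:
    """Cross-validation / bootstrap diagnostics of a calibration fit."""

    r2_loocv: float | None = None
    rmse: float | None = None
    ci95: tuple | None = None
    n_train: int | None = None
    n_test: int | None = None
    n_boot: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rmse is not None and self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.ci95 is not None and self.ci95[0] > self.ci95[1]:
            raise ValueError("ci95 low must be <= high")


@dataclass
class SlopeProfile:
    """Per-wavelength linear response of reflectance to wax load.

    ``slope`` is d(reflectance fraction)/d(mg/dm^2); ``p_value`` is the
    two-sided test of slope = 0.
    """

    wavelengths_nm: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    p_value: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        if not (len(self.slope) == len(self.intercept) == len(self.p_value) == n):
            raise ValueError("profile arrays must share the grid length")


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for a design matrix (no intercept column added)."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def loocv_r2(x, y) -> float:
    """Leave-one-out cross-validated R^2 of the simple regression y ~ x.

    R^2 = 1 - PRESS / SST, with PRESS the sum of squared single-deletion
    prediction errors.  Uses the hat-matrix identity
    e_(i) = e_i / (1 - h_ii), which is algebraically exact for least squares.
    May be negative when the model predicts worse than the mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("LOOCV needs n >= 3")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("zero total sum of squares: LOOCV R^2 undefined")
    X = np.column_stack([np.ones(n), x])
    coef = _ols(X, y)
    resid = y - X @ coef
    # leverage h_ii = diag(X (X'X)^-1 X')
    XtX_inv = np.linalg.pinv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    press = np.sum((resid / (1.0 - h)) ** 2)
    return float(1.0 - press / sst)


def fit_index_calibration(ew, index, name: str = "user-index"):
    """Fit the calibration line ``index = a + B * ew`` for inverse prediction.

    Returns the :class:`~waxspec.prediction.IndexCalibration` (calibration
    direction, used for inversion) together with :class:`FitDiagnostics`
    whose ``r2_loocv`` is computed in the trait-on-index direction
    ``ew = b0 + b1 * index`` — the direction used to rank candidate indices.
    """
    ew = np.asarray(ew, dtype=float)
    index = np.asarray(index, dtype=float)
    if ew.size != index.size or ew.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.std(ew) == 0:
        raise ValueError("degenerate design: wax values have zero variance")
    X = np.column_stack([np.ones(ew.size), ew])
    a, B = _ols(X, index)
    if B == 0:
        raise ValueError("fitted slope is exactly zero; calibration not invertible")
    r2cv = loocv_r2(index, ew)
    fitted = X @ np.array([a, B])
    rmse_cal = float(np.sqrt(np.mean((index - fitted) ** 2)))
    calib = IndexCalibration(name, float(a), float(B), r2=r2cv, rmse_mg_dm2=None)
    diag = FitDiagnostics(r2_loocv=r2cv, rmse=rmse_cal, n_train=int(ew.size))
    return calib, diag


class IndexCalibrator(RegressorMixin, BaseEstimator):
    """Inverse-prediction calibration of a spectral index against wax load.

    ``fit(X, y)`` takes index values (n_samples, 1) and wax loads y and fits
    the calibration line index = a + B * ew; ``predict(X)`` inverts it,
    ew_hat = (index - a) / B.

    Attributes
    ----------
    a_ : float        intercept of the calibration line (index units)
    b_ : float        slope (index units per mg/dm^2)
    r2_loocv_ : float leave-one-out R^2 of the trait-on-index direction
    """

    def __init__(self, name: str = "user-index"):
        self.name = name

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.shape[1] != 1:
            raise ValueError("IndexCalibrator expects a single index column")
        y = np.asarray(y, dtype=float)
        calib, diag = fit_index_calibration(y, X[:, 0], name=self.name)
        self.a_ = calib.a
        self.b_ = calib.B
        self.r2_loocv_ = diag.r2_loocv
        self.calibration_ = calib
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return (X - self.a_) / self.b_


def bootstrap_rmse(
    ew,
    index,
    n_boot: int = 1000,
    train_frac: float = 2.0 / 3.0,
    seed: int | None = None,
) -> FitDiagnostics:
    """Bootstrap RMSE of inverse prediction for one index.

    Each replicate draws a random calibration subset (``train_frac`` of the
    rows), fits index = b0 + b1 * ew on it, inverse-predicts wax on the
    held-out rows, and records the RMSE against the measured wax.  Returns
    the mean RMSE with its 2.5/97.5 percentile interval; fully reproducible
    from ``seed``.
    """
    ew = np.asarray(ew, dtype=float)
    index = np.asarray(index, dtype=float)
    n = ew.size
    if n < 6:
        raise ValueError("bootstrap needs n >= 6")
    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(train_frac * n)))
    if n_train >= n:
        n_train = n - 1
    rmses = np.empty(n_boot)
    for b in range(n_boot):
        for _attempt in range(100):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if np.std(ew[tr]) > 0:
                X = np.column_stack([np.ones(tr.size), ew[tr]])
                b0, b1 = _ols(X, index[tr])
                if b1 != 0:
                    break
        else:
            raise RuntimeError("could not draw a non-degenerate train split")
        ew_hat = (index[te] - b0) / b1
        rmses[b] = np.sqrt(np.mean((ew[te] - ew_hat) ** 2))
    lo, hi = np.percentile(rmses, [2.5, 97.5])
    return FitDiagnostics(
        rmse=float(rmses.mean()),
        ci95=(float(lo), float(hi)),
        n_train=n_train,
        n_test=n - n_train,
        n_boot=n_boot,
        seed=seed,
    )


def per_band_slopes(spectra, ew, wavelengths_nm=None) -> SlopeProfile:
    """Per-band OLS of reflectance on wax load.

    ``spectra`` is (samples x bands); the returned slope is the reflectance
    change (fraction) per mg/dm^2 of wax at each band, with a two-sided
    p-value for slope = 0.
    """
    spectra = np.asarray(spectra, dtype=float)
    ew = np.asarray(ew, dtype=float)
    n, p = spectra.shape
    if n < 3:
        raise ValueError("need at least 3 samples per band")
    if np.std(ew) == 0:
        raise ValueError("wax values are constant; slopes undefined")
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(p, dtype=float)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    xc = ew - ew.mean()
    sxx = np.sum(xc**2)
    slope = (xc @ (spectra - spectra.mean(axis=0))) / sxx
    intercept = spectra.mean(axis=0) - slope * ew.mean()
    fitted = np.outer(ew, slope) + intercept
    resid = spectra - fitted
    dof = n - 2
    s2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slope / se, np.inf * np.sign(slope + (slope == 0)))
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pval = np.where(se > 0, pval, 0.0)
    return SlopeProfile(wavelengths_nm, slope, intercept, np.clip(pval, 0.0, 1.0))


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------


class NIPALSPLSRegressor(RegressorMixin, BaseEstimator):
    """PLS1 regression via the NIPALS algorithm.

    Decomposes mean-centered predictors as X = T P' + E, with score columns
    T mutually orthogonal, extracting components that maximise covariance
    with the response.  Mean-centering only by default — reflectance bands
    share units, so unit-variance scaling is optional.

    Parameters
    ----------
    n_components : int
        Number of latent components to extract.
    scale : bool
        If True, also divide each column by its standard deviation.

    Attributes
    ----------
    x_scores_ : (n, k) array    score matrix T
    x_loadings_ : (p, k) array  loading matrix P
    x_weights_ : (p, k) array   weight matrix W
    y_loadings_ : (k,) array    response loadings q
    residual_ : (n, p) array    E = X_centered - T P'
    coef_ : (p,) array          regression coefficients on the original scale
    intercept_ : float
    y_variance_explained_ : (k,) array
        Percent of the response variance explained by each component.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        k = self.n_components
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k >= n:
            raise ValueError("ill-posed: n_components must be < n_samples")
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        self.x_std_ = np.where(self.x_std_ == 0, 1.0, self.x_std_)
        self.y_mean_ = y.mean()
        Xc = (X - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_

        T = np.zeros((n, k))
        P = np.zeros((p, k))
        W = np.zeros((p, k))
        q = np.zeros(k)
        Xd, yd = Xc.copy(), yc.copy()
        sst = np.sum(yc**2)
        explained = np.zeros(k)
        for j in range(k):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw == 0:  # response fully deflated; stop extracting
                k = j
                break
            w /= nw
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                k = j
                break
            pj = Xd.T @ t / tt
            qj = yd @ t / tt
            Xd -= np.outer(t, pj)
            yd -= qj * t
            T[:, j], P[:, j], W[:, j], q[j] = t, pj, w, qj
            explained[j] = 100.0 * qj**2 * tt / sst if sst > 0 else 0.0
        T, P, W, q, explained = T[:, :k], P[:, :k], W[:, :k], q[:k], explained[:k]
        self.n_components_ = k
        self.x_scores_, self.x_loadings_, self.x_weights_, self.y_loadings_ = T, P, W, q
        self.residual_ = Xd
        # B = W (P'W)^-1 q maps centered X to centered y
        R = W @ np.linalg.pinv(P.T @ W)
        coef_centered = R @ q
        self.coef_ = coef_centered / self.x_std_
        self.intercept_ = float(self.y_mean_ - self.x_mean_ @ self.coef_)
        self.y_variance_explained_ = explained
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def influential_wavelengths(self, wavelengths_nm, top: int = 10) -> np.ndarray:
        """Wavelengths ranked by |regression coefficient|, largest first."""
        check_is_fitted(self, "coef_")
        order = np.argsort(-np.abs(self.coef_))
        return np.asarray(wavelengths_nm, dtype=float)[order[:top]]


@dataclass
class PLSRFitResult:
    """Outcome of a train/validation PLS calibration run."""

    model: NIPALSPLSRegressor
    n_components: int
    rmsep_per_components: np.ndarray  # LOOCV RMSEP on the training split
    y_variance_explained: np.ndarray
    influential_wavelengths: np.ndarray
    val_predictions: np.ndarray
    val_observed: np.ndarray
    val_rmse: float
    train_idx: np.ndarray
    val_idx: np.ndarray


def _loocv_rmsep_pls(X, y, k: int) -> float:
    n = X.shape[0]
    errs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        m = NIPALSPLSRegressor(n_components=k).fit(X[mask], y[mask])
        errs[i] = y[i] - m.predict(X[i : i + 1])[0]
    return float(np.sqrt(np.mean(errs**2)))


def plsr_fit(
    X,
    y,
    max_components: int = 10,
    seed: int | None = None,
    val_frac: float = 1.0 / 3.0,
    wavelengths_nm=None,
) -> PLSRFitResult:
    """Train/validate a NIPALS PLS1 wax calibration.

    Rows are split 2/3 train, 1/3 validation (seeded); the component count is
    chosen by minimum LOOCV RMSEP on the training split; predictions on the
    validation rows are returned together with the per-component percent of
    response variance explained and a coefficient-magnitude ranking of
    wavelengths.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(val_frac * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if max_components >= train_idx.size:
        raise ValueError("ill-posed: max_components must be < n_train")
    Xtr, ytr = X[train_idx], y[train_idx]
    rmseps = np.array(
        [_loocv_rmsep_pls(Xtr, ytr, k) for k in range(1, max_components + 1)]
    )
    best_k = int(np.argmin(rmseps)) + 1
    model = NIPALSPLSRegressor(n_components=best_k).fit(Xtr, ytr)
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(X.shape[1], dtype=float)
    val_pred = model.predict(X[val_idx])
    val_rmse = float(np.sqrt(np.mean((y[val_idx] - val_pred) ** 2)))
    return PLSRFitResult(
        model=model,
        n_components=best_k,
        rmsep_per_components=rmseps,
        y_variance_explained=model.y_variance_explained_,
        influential_wavelengths=model.influential_wavelengths(wavelengths_nm),
        val_predictions=val_pred,
        val_observed=y[val_idx],
        val_rmse=val_rmse,
        train_idx=train_idx,
        val_idx=val_idx,
    )


# ---------------------------------------------------------------------------
# Stepwise regression with Mallows' Cp
# ---------------------------------------------------------------------------


def _sse(X, y, cols) -> float:
    D = np.column_stack([np.ones(y.size)] + [X[:, j] for j in cols])
    coef = _ols(D, y)
    r = y - D @ coef
    return float(r @ r)


def mallows_cp(sse_p: float, sigma2_full: float, n: int, n_params: int) -> float:
    """Mallows' Cp = SSE_p / sigma2_full - n + 2 p, p counting the intercept."""
    return sse_p / sigma2_full - n + 2 * n_params


class StepwiseCpRegressor(RegressorMixin, BaseEstimator):
    """Forward stepwise regression with backward elimination and Cp selection.

    Candidates enter on the significance of their partial F-statistic
    (p < ``alpha_enter``) and leave when no longer significant
    (p > ``alpha_remove``).  Every model visited along the path is scored by
    Mallows' Cp (error variance taken from the full model); the reported fit
    is the Cp-minimising visited model, refit by OLS.

    Attributes
    ----------
    selected_ : list of int       column indices of the chosen model
    coef_ : array                 coefficients of the chosen model
    intercept_ : float
    cp_trace_ : list of (tuple, float)   (columns, Cp) per visited model
    f_trace_ : list of dict       partial-F record per inclusion/removal step
    """

    def __init__(self, alpha_enter: float = 0.15, alpha_remove: float = 0.15):
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n <= p + 2:
            raise ValueError("need n > n_candidates + 2 for the full-model variance")
        # drop exactly collinear candidates from the full model's sigma^2
        keep = []
        for j in range(p):
            test = keep + [j]
            D = np.column_stack([np.ones(n)] + [X[:, c] for c in test])
            if np.linalg.matrix_rank(D) == D.shape[1]:
                keep.append(j)
        if len(keep) < p:
            import warnings

            dropped = sorted(set(range(p)) - set(keep))
            warnings.warn(f"dropping collinear candidate column(s) {dropped}")
        candidates = keep
        sse_full = _sse(X, y, candidates)
        dof_full = n - (len(candidates) + 1)
        sigma2_full = sse_full / dof_full
        if sigma2_full <= 0:
            sigma2_full = np.finfo(float).tiny

        selected: list[int] = []
        cp_trace: list = []
        f_trace: list = []

        def record(cols):
            cp = mallows_cp(_sse(X, y, cols), sigma2_full, n, len(cols) + 1)
            cp_trace.append((tuple(sorted(cols)), cp))

        record(selected)
        # numerical floor: an SSE this far below the total variation is a
        # perfect fit; partial F-tests on rounding residue are meaningless
        sse_floor = 1e-12 * float(np.sum((y - y.mean()) ** 2))
        changed = True
        while changed:
            changed = False
            # forward step: best candidate by partial F
            best = None
            sse_cur = _sse(X, y, selected)
            if sse_cur <= sse_floor:
                break
            for j in candidates:
                if j in selected:
                    continue
                cols = selected + [j]
                sse_new = _sse(X, y, cols)
                dof = n - (len(cols) + 1)
                if dof <= 0 or sse_new >= sse_cur:
                    continue
                F = (sse_cur - sse_new) / (sse_new / dof)
                pv = float(stats.f.sf(F, 1, dof))
                if pv < self.alpha_enter and (best is None or pv < best[1]):
                    best = (j, pv, F)
            if best is not None:
                j, pv, F = best
                selected.append(j)
                f_trace.append({"action": "enter", "column": j, "F": F, "p": pv})
                record(selected)
                changed = True
            # backward step: drop the least significant term
            while len(selected) > 1:
                worst = None
                sse_cur = _sse(X, y, selected)
                dof = n - (len(selected) + 1)
                for j in selected:
                    cols = [c for c in selected if c != j]
                    sse_red = _sse(X, y, cols)
                    F = (sse_red - sse_cur) / (sse_cur / dof)
                    pv = float(stats.f.sf(F, 1, dof))
                    if pv > self.alpha_remove and (worst is None or pv > worst[1]):
                        worst = (j, pv, F)
                if worst is None:
                    break
                j, pv, F = worst
                selected.remove(j)
                f_trace.append({"action": "remove", "column": j, "F": F, "p": pv})
                record(selected)
                changed = True

        best_cols, best_cp = min(cp_trace, key=lambda t: t[1])
        self.selected_ = list(best_cols)
        D = np.column_stack([np.ones(n)] + [X[:, c] for c in self.selected_])
        coef = _ols(D, y)
        self.intercept_ = float(coef[0])
        self.coef_full_ = np.zeros(p)
        for c, b in zip(self.selected_, coef[1:]):
            self.coef_full_[c] = b
        self.coef_ = coef[1:]
        self.cp_ = best_cp
        self.cp_trace_ = cp_trace
        self.f_trace_ = f_trace
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "selected_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_full_


@dataclass
class StepwiseResult:
    """Selected band-linear model with its Cp path and hold-out RMSE."""

    selected: list
    coefficients: np.ndarray
    intercept: float
    cp_trace: list
    f_trace: list
    rmse_holdout: float
    model: StepwiseCpRegressor
    train_idx: np.ndarray
    test_idx: np.ndarray


def stepwise_cp(
    X,
    y,
    alpha_enter: float = 0.15,
    alpha_remove: float = 0.15,
    train_frac: float = 0.6,
    seed: int | None = None,
    wavelengths_nm=None,
) -> StepwiseResult:
    """Stepwise band selection on a 60 % training split; RMSE on the rest.

    ``selected`` holds wavelengths (nm) when a grid is given, else column
    indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = max(3, int(round(train_frac * n)))
    tr, te = perm[:n_train], perm[n_train:]
    model = StepwiseCpRegressor(alpha_enter, alpha_remove).fit(X[tr], y[tr])
    if te.size:
        rmse = float(np.sqrt(np.mean((y[te] - model.predict(X[te])) ** 2)))
    else:
        rmse = float("nan")
    if wavelengths_nm is not None:
        wl = np.asarray(wavelengths_nm, dtype=float)
        selected = [float(wl[j]) for j in model.selected_]
    else:
        selected = list(model.selected_)
    return StepwiseResult(
        selected=selected,
        coefficients=model.coef_.copy(),
        intercept=model.intercept_,
        cp_trace=model.cp_trace_,
        f_trace=model.f_trace_,
        rmse_holdout=rmse,
        model=model,
        train_idx=tr,
        test_idx=te,
    )
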