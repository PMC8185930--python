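"""Calibration machinery vs independent oracles: LOOCV, bootstrap, PLS, stepwise."""

import itertools

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from waxspec.calibration import (
    IndexCalibrator,
    NIPALSPLSRegressor,
    StepwiseCpRegressor,
    bootstrap_rmse,
    fit_index_calibration,
    loocv_r2,
    mallows_cp,
    per_band_slopes,
    plsr_fit,
    stepwise_cp,
)
from waxspec.synthetic import baseline_leaf_spectrum, default_grid, default_wax_profile


def brute_force_loocv_r2(x, y):
    """Independent oracle: literal n single-deletion refits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    press = 0.0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        A = np.column_stack([np.ones(n - 1), x[mask]])
        b0, b1 = np.linalg.lstsq(A, y[mask], rcond=None)[0]
        press += (y[i] - (b0 + b1 * x[i])) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


class TestLoocv:
    def test_exact_line_gives_one(self):
        x = np.arange(10.0)
        assert loocv_r2(x, 2.0 + 0.3 * x) == pytest.approx(1.0)

    def test_orthogonal_response_negative(self):
        # oracle: brute-force 4 refits
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([-1.0, -1.0, 1.0, 1.0])  # uncorrelated with x
        val = loocv_r2(x, y)
        assert val < 0
        assert val == pytest.approx(brute_force_loocv_r2(x, y), abs=1e-10)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=25)
        y = 1.0 + 0.5 * x + rng.normal(scale=0.3, size=25)
        assert loocv_r2(x, y) == pytest.approx(brute_force_loocv_r2(x, y), abs=1e-10)

    def test_zero_sst_error(self):
        with pytest.raises(ValueError, match="undefined"):
            loocv_r2(np.arange(5.0), np.ones(5))


class TestFitIndexCalibration:
    def test_noise_free_recovery(self):
        ew = np.linspace(0.5, 4.0, 20)
        index = 0.213 + 0.04 * ew
        calib, diag = fit_index_calibration(ew, index)
        assert calib.a == pytest.approx(0.213, abs=1e-10)
        assert calib.B == pytest.approx(0.04, abs=1e-12)
        assert diag.r2_loocv == pytest.approx(1.0)

    def test_null_relation_has_no_cv_skill(self):
        rng = np.random.default_rng(123)
        ew = rng.normal(2.0, 0.5, 200)
        index = rng.normal(0.3, 0.05, 200)  # independent of ew
        _, diag = fit_index_calibration(ew, index)
        assert diag.r2_loocv <= 0.05

    def test_degenerate_design_errors(self):
        with pytest.raises(ValueError):
            fit_index_calibration(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            fit_index_calibration(np.arange(3.0), np.arange(3.0))

    def test_estimator_wrapper_inverts(self):
        ew = np.linspace(0.5, 4.0, 30)
        index = 0.1 + 0.05 * ew
        est = IndexCalibrator().fit(index.reshape(-1, 1), ew)
        assert np.allclose(est.predict(index.reshape(-1, 1)), ew, atol=1e-10)
        assert est.get_params() == {"name": "user-index"}


class TestBootstrapRmse:
    def test_noise_free_zero_rmse(self):
        ew = np.linspace(0.5, 4.0, 30)
        index = 0.1 + 0.05 * ew
        diag = bootstrap_rmse(ew, index, n_boot=50, seed=0)
        assert diag.rmse == pytest.approx(0.0, abs=1e-10)
        assert diag.ci95 == pytest.approx((0.0, 0.0), abs=1e-10)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        ew = rng.uniform(0.5, 4.0, 40)
        index = 0.1 + 0.05 * ew + rng.normal(0, 0.02, 40)
        d1 = bootstrap_rmse(ew, index, n_boot=200, seed=99)
        d2 = bootstrap_rmse(ew, index, n_boot=200, seed=99)
        assert d1.rmse == d2.rmse and d1.ci95 == d2.ci95

    def test_rmse_tracks_noise_over_slope(self):
        # delta method: inverse-prediction error ~ sigma / |B|
        rng = np.random.default_rng(8)
        a, B, sigma = 0.1, 0.05, 0.01
        ew = rng.uniform(0.5, 4.0, 90)
        index = a + B * ew + rng.normal(0, sigma, 90)
        diag = bootstrap_rmse(ew, index, n_boot=500, seed=2)
        assert diag.rmse == pytest.approx(sigma / B, rel=0.15)

    def test_ci_width_shrinks_with_noise(self):
        rng = np.random.default_rng(9)
        ew = rng.uniform(0.5, 4.0, 60)
        widths = []
        for sigma in (0.0, 0.01, 0.05):
            index = 0.1 + 0.05 * ew + rng.normal(0, sigma, 60)
            d = bootstrap_rmse(ew, index, n_boot=300, seed=5)
            widths.append(d.ci95[1] - d.ci95[0])
        assert widths[0] <= widths[1] <= widths[2]


class TestPerBandSlopes:
    def test_recovers_injected_profile_exactly(self):
        grid = default_grid()
        profile = default_wax_profile()
        base = baseline_leaf_spectrum(grid).reflectance
        ew = np.linspace(0.5, 4.0, 12)
        panel = base + np.outer(ew, profile(grid))
        prof = per_band_slopes(panel, ew, grid)
        assert np.allclose(prof.slope, profile(grid), atol=1e-12)
        i780 = np.argmin(np.abs(grid - 780))
        assert prof.slope[i780] == pytest.approx(0.015, abs=1e-12)

    def test_injected_negative_red_edge_slope(self):
        grid = default_grid()
        base = baseline_leaf_spectrum(grid).reflectance
        inject = np.zeros(grid.size)
        i717 = np.argmin(np.abs(grid - 717))
        inject[i717] = -0.008
        ew = np.linspace(0.5, 4.0, 10)
        prof = per_band_slopes(base + np.outer(ew, inject), ew, grid)
        assert prof.slope[i717] == pytest.approx(-0.008, abs=1e-12)

    def test_within_3se_under_noise(self):
        grid = default_grid()
        profile = default_wax_profile()
        truth = profile(grid)
        base = baseline_leaf_spectrum(grid).reflectance
        rng = np.random.default_rng(21)
        ew = rng.uniform(0.5, 4.0, 100)
        panel = base + np.outer(ew, truth) + rng.normal(0, 0.005, (100, grid.size))
        prof = per_band_slopes(panel, ew, grid)
        xc = ew - ew.mean()
        se = 0.005 / np.sqrt(np.sum(xc**2))  # known-sigma slope SE
        frac_within = np.mean(np.abs(prof.slope - truth) <= 3 * se)
        assert frac_within > 0.95

    def test_constant_ew_errors(self):
        with pytest.raises(ValueError, match="constant"):
            per_band_slopes(np.random.default_rng(0).uniform(size=(5, 3)), np.ones(5))


class TestNIPALSPLS:
    def make_data(self, n=30, p=8, seed=3, noise=0.1):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + rng.normal(scale=noise, size=n)
        return X, y

    def test_reconstruction_identity_and_orthogonal_scores(self):
        X, y = self.make_data()
        m = NIPALSPLSRegressor(n_components=4).fit(X, y)
        Xc = X - X.mean(axis=0)
        assert np.allclose(Xc, m.x_scores_ @ m.x_loadings_.T + m.residual_, atol=1e-10)
        TtT = m.x_scores_.T @ m.x_scores_
        off = TtT - np.diag(np.diag(TtT))
        assert np.max(np.abs(off)) < 1e-8

    def test_rank_one_collapses_to_simple_regression(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=20)
        X = np.outer(t, rng.uniform(0.5, 2.0, 5))  # all bands proportional
        y = 3.0 * t + 1.0
        m = NIPALSPLSRegressor(n_components=1).fit(X, y)
        b0, b1 = np.linalg.lstsq(
            np.column_stack([np.ones(20), X[:, 0]]), y, rcond=None
        )[0]
        assert np.allclose(m.predict(X), b0 + b1 * X[:, 0], atol=1e-10)

    def test_full_rank_equals_ols(self):
        # oracle: normal equations on the full-rank design
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        m = NIPALSPLSRegressor(n_components=5).fit(X, y)
        A = np.column_stack([np.ones(12), X])
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(m.predict(X), A @ coef, atol=1e-8)

    def test_matches_sklearn_pls(self):
        X, y = self.make_data(seed=14)
        for k in (1, 2, 3):
            ours = NIPALSPLSRegressor(n_components=k).fit(X, y)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.allclose(
                ours.predict(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_y_variance_explained_monotone_bounded(self):
        X, y = self.make_data(seed=15)
        m = NIPALSPLSRegressor(n_components=6).fit(X, y)
        cum = np.cumsum(m.y_variance_explained_)
        assert np.all(np.diff(cum) >= -1e-10)
        assert cum[-1] <= 100.0 + 1e-8
        assert np.all(m.y_variance_explained_ >= -1e-10)

    def test_ill_posed_errors(self):
        X, y = self.make_data(n=5, p=3)
        with pytest.raises(ValueError, match="ill-posed"):
            NIPALSPLSRegressor(n_components=5).fit(X, y)

    def test_plsr_fit_selects_components_and_validates(self):
        rng = np.random.default_rng(31)
        n, p = 45, 10
        X = rng.normal(size=(n, p))
        y = 2.0 * X[:, 0] - 1.0 * X[:, 4] + rng.normal(scale=0.1, size=n)
        res = plsr_fit(X, y, max_components=5, seed=1, wavelengths_nm=400 + 3 * np.arange(p))
        assert 1 <= res.n_components <= 5
        assert res.val_predictions.shape == res.val_observed.shape
        assert res.val_rmse < np.std(y)  # beats the mean predictor
        # the two truly informative bands rank among the most influential
        assert {400.0, 412.0} <= set(res.influential_wavelengths[:4])


def exhaustive_best_subset_cp(X, y):
    """Oracle: enumerate every subset, score by Mallows' Cp."""
    n, p = X.shape
    sse_full = _sse(X, y, list(range(p)))
    sigma2 = sse_full / (n - p - 1)
    best = None
    for k in range(p + 1):
        for cols in itertools.combinations(range(p), k):
            cp = mallows_cp(_sse(X, y, list(cols)), sigma2, n, k + 1)
            if best is None or cp < best[1]:
                best = (set(cols), cp)
    return best


def _sse(X, y, cols):
    D = np.column_stack([np.ones(y.size)] + [X[:, j] for j in cols])
    r = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    return float(r @ r)


class TestStepwiseCp:
    def test_single_true_band_selected_with_its_coefficient(self):
        rng = np.random.default_rng(17)
        n = 60
        X = rng.normal(size=(n, 8))
        y = 5.0 * X[:, 0]  # exact relation, other 7 bands pure noise
        m = StepwiseCpRegressor().fit(X, y)
        assert m.selected_ == [0]
        assert m.coef_[0] == pytest.approx(5.0, abs=1e-10)
        # exhaustive oracle agrees
        best_cols, _ = exhaustive_best_subset_cp(X, y)
        assert set(m.selected_) == best_cols

    @pytest.mark.parametrize("seed", [2, 7, 11])
    def test_matches_exhaustive_oracle_on_orthogonal_signal(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        X = rng.normal(size=(n, 6))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 3] + rng.normal(scale=0.5, size=n)
        m = StepwiseCpRegressor().fit(X, y)
        best_cols, best_cp = exhaustive_best_subset_cp(X, y)
        assert set(m.selected_) == best_cols
        assert m.cp_ == pytest.approx(best_cp, abs=1e-8)

    def test_cp_of_full_model_is_its_parameter_count(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(40, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 2.0]) + rng.normal(scale=1.0, size=40)
        sse_full = _sse(X, y, [0, 1, 2, 3])
        sigma2 = sse_full / (40 - 5)
        assert mallows_cp(sse_full, sigma2, 40, 5) == pytest.approx(5.0)

    def test_null_entry_rate_matches_best_of_k_theory(self):
        # Under pure noise the first forward step admits a term when the best
        # of k=8 partial-F p-values is below alpha; for near-independent
        # candidates that happens with probability about 1 - (1-alpha)^8.
        alpha = 0.15
        runs, entered = 200, 0
        for seed in range(runs):
            rng = np.random.default_rng(10_000 + seed)
            X = rng.normal(size=(60, 8))
            y = rng.normal(size=60)
            m = StepwiseCpRegressor(alpha_enter=alpha, alpha_remove=alpha).fit(X, y)
            entered += bool(m.f_trace_ and m.f_trace_[0]["action"] == "enter")
        expect = 1.0 - (1.0 - alpha) ** 8
        se = np.sqrt(expect * (1 - expect) / runs)
        assert abs(entered / runs - expect) < 4 * se + 0.02

    def test_collinear_candidates_dropped_with_warning(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(50, 4))
        X = np.column_stack([X, X[:, 0] * 2.0])  # exact duplicate direction
        y = X[:, 0] + rng.normal(scale=0.1, size=50)
        with pytest.warns(UserWarning, match="collinear"):
            m = StepwiseCpRegressor().fit(X, y)
        assert 4 not in m.selected_

    def test_wrapper_reports_holdout_rmse_and_wavelengths(self):
        rng = np.random.default_rng(29)
        n = 100
        X = rng.normal(size=(n, 8))
        y = 4.0 * X[:, 2] + rng.normal(scale=0.3, size=n)
        wl = 400.0 + 3.0 * np.arange(8)
        res = stepwise_cp(X, y, seed=3, wavelengths_nm=wl)
        assert 406.0 in res.selected
        assert res.rmse_holdout == pytest.approx(0.3, rel=0.6)
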