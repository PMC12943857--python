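import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from agbmap.geostat import (
    CoregionalizationModel,
    VariogramModel,
    co_kriging,
    cross_semivariogram,
    empirical_semivariogram,
    fit_lmc,
    fit_variogram,
    loo_diagnostics,
    ordinary_kriging,
    variogram_value,
)
from agbmap.synthetic import simulate_grf_points


def gauss_solve(a, b):
    """Textbook Gaussian elimination with partial pivoting (test oracle)."""
    a = a.astype(float).copy()
    b = b.astype(float).copy()
    n = len(a)
    for col in range(n):
        piv = col + int(np.argmax(np.abs(a[col:, col])))
        if piv != col:
            a[[col, piv]] = a[[piv, col]]
            b[[col, piv]] = b[[piv, col]]
        for row in range(col + 1, n):
            f = a[row, col] / a[col, col]
            a[row, col:] -= f * a[col, col:]
            b[row] -= f * b[col]
    x = np.zeros_like(b)
    for row in range(n - 1, -1, -1):
        x[row] = (b[row] - a[row, row + 1:] @ x[row + 1:]) / a[row, row]
    return x


def ok_oracle(model, sp, sv, qp):
    """Assemble and solve the full OK system independently."""
    n = len(sp)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = variogram_value(model, squareform(pdist(sp)))
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    preds = []
    for q in qp:
        b = np.append(variogram_value(model, cdist(sp, q[None])).ravel(), 1.0)
        lam = gauss_solve(a, b)
        preds.append(lam[:n] @ sv)
    return np.array(preds)


EXP = VariogramModel("exponential", nugget=0.5, partial_sill=2.0, effective_range=40.0)


class TestVariogramValue:
    def test_zero_at_origin(self):
        assert variogram_value(EXP, 0.0) == 0.0

    def test_sill_limit(self):
        assert np.isclose(variogram_value(EXP, 1e7), EXP.sill)

    def test_value_at_effective_range(self):
        expect = EXP.nugget + EXP.partial_sill * (1 - np.exp(-3.0))
        assert np.isclose(variogram_value(EXP, 40.0), expect)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            variogram_value(EXP, -1.0)

    @pytest.mark.parametrize("family", ["exponential", "spherical", "gaussian"])
    def test_nondecreasing(self, family):
        m = VariogramModel(family, 0.3, 1.5, 50.0)
        h = np.linspace(0.01, 200.0, 300)
        g = variogram_value(m, h)
        assert (np.diff(g) >= -1e-12).all()

    def test_invariants(self):
        assert 0.0 <= EXP.nugget_sill_ratio <= 1.0
        with pytest.raises(ValueError):
            VariogramModel("exponential", -0.1, 1.0, 10.0)


class TestEmpiricalSemivariogram:
    def test_constant_field_zero(self):
        pts = np.random.default_rng(0).uniform(0, 100, (30, 2))
        emp = empirical_semivariogram(pts, np.full(30, 3.0), n_lags=5)
        _, g, _ = emp.valid()
        assert np.allclose(g, 0.0)

    def test_single_pair_arithmetic(self):
        emp = empirical_semivariogram(np.array([[0.0, 0.0], [1.0, 0.0]]),
                                      np.array([0.0, 2.0]), n_lags=1, max_dist=2.0)
        assert np.isclose(emp.gamma_hat[0], 2.0)
        assert emp.pair_counts[0] == 1

    def test_iid_noise_flat_at_variance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1000, (500, 2))
        z = rng.normal(0, 3.0, 500)
        emp = empirical_semivariogram(pts, z, n_lags=10)
        h, g, n = emp.valid()
        well = n > 2000
        # every well-populated bin sits at the (realized) process variance
        assert (np.abs(g[well] - z.var()) / z.var() < 0.10).all()

    def test_empty_bin_is_missing_not_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [100.0, 0.0]])
        emp = empirical_semivariogram(pts, np.array([1.0, 2.0, 3.0]),
                                      n_lags=10, max_dist=100.0)
        assert np.isnan(emp.gamma_hat[3])
        assert emp.pair_counts[3] == 0


class TestCrossSemivariogram:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (50, 2))
        z = rng.normal(size=50)
        direct = empirical_semivariogram(pts, z, n_lags=6)
        same = cross_semivariogram(pts, z, z, n_lags=6)
        neg = cross_semivariogram(pts, z, -z, n_lags=6)
        assert np.allclose(same.gamma_hat, direct.gamma_hat, equal_nan=True)
        assert np.allclose(neg.gamma_hat, -direct.gamma_hat, equal_nan=True)

    def test_independent_fields_near_zero(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1000, (400, 2))
        z1 = rng.normal(0, 1, 400)
        z2 = rng.normal(0, 1, 400)
        emp = cross_semivariogram(pts, z1, z2, n_lags=8)
        d1 = empirical_semivariogram(pts, z1, n_lags=8)
        d2 = empirical_semivariogram(pts, z2, n_lags=8)
        _, g, n = emp.valid()
        scale = np.sqrt(d1.gamma_hat[d1.pair_counts > 0] * d2.gamma_hat[d2.pair_counts > 0])
        # cross structure is a small fraction of the direct structures
        assert (np.abs(g[n > 1000]) < 0.2 * scale[n > 1000]).all()


class TestFitVariogram:
    def test_exact_recovery_from_model_bins(self):
        """Noise-free bins generated from a known exponential model are
        recovered to better than 1% (nugget 132.63, sill 146.41, range
        54,556 m)."""
        truth = VariogramModel("exponential", 132.63, 146.41 - 132.63, 54556.27)
        h = np.linspace(2000.0, 60000.0, 15)
        from agbmap.geostat import EmpiricalVariogram
        emp = EmpiricalVariogram(h, variogram_value(truth, h),
                                 np.full(15, 500), 60000.0)
        fit = fit_variogram(emp, "exponential")
        assert abs(fit.nugget - truth.nugget) / truth.nugget < 0.01
        assert abs(fit.sill - truth.sill) / truth.sill < 0.01
        assert abs(fit.effective_range - truth.effective_range) / truth.effective_range < 0.01
        assert round(fit.nugget_sill_ratio, 2) == 0.91

    def test_pure_nugget_degenerates_gracefully(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 1000, (300, 2))
        z = rng.normal(0, 2.0, 300)
        emp = empirical_semivariogram(pts, z, n_lags=10)
        fit = fit_variogram(emp)
        assert fit.nugget_sill_ratio > 0.9

    def test_grf_parameter_recovery_median(self):
        """Median recovered nugget/sill over 20 simulated fields is within
        0.1 of the truth and the median range within 50%."""
        truth = VariogramModel("exponential", 162.78, 186.92 - 162.78, 35026.50)
        rng = np.random.default_rng(5)
        ratios, ranges = [], []
        for seed in range(20):
            pts = rng.uniform(0, 131000, (800, 2))
            z = simulate_grf_points(pts, truth, seed=seed)
            # lags past ~2x the range only add noise to the fit
            emp = empirical_semivariogram(pts, z, n_lags=14, max_dist=70000.0)
            fit = fit_variogram(emp)
            ratios.append(fit.nugget_sill_ratio)
            ranges.append(fit.effective_range)
        assert abs(np.median(ratios) - truth.nugget_sill_ratio) < 0.1
        assert abs(np.median(ranges) - truth.effective_range) / truth.effective_range < 0.5


class TestOrdinaryKriging:
    def test_exact_interpolation_with_zero_nugget(self):
        model = VariogramModel("exponential", 0.0, 2.0, 50.0)
        rng = np.random.default_rng(6)
        sp = rng.uniform(0, 100, (15, 2))
        sv = rng.normal(100, 10, 15)
        out = ordinary_kriging(model, sp, sv, sp[:5])
        assert np.allclose(out.predictions, sv[:5], atol=1e-8)
        assert np.allclose(out.variance[:5], 0.0, atol=1e-8)

    def test_symmetry_two_samples(self):
        model = EXP
        sp = np.array([[0.0, 0.0], [10.0, 0.0]])
        sv = np.array([4.0, 8.0])
        out = ordinary_kriging(model, sp, sv, np.array([[5.0, 3.0]]))
        assert np.isclose(out.predictions[0], 6.0)

    def test_matches_dense_gaussian_elimination_oracle(self):
        rng = np.random.default_rng(7)
        sp = rng.uniform(0, 200, (20, 2))
        sv = rng.normal(50, 12, 20)
        qp = rng.uniform(0, 200, (5, 2))
        out = ordinary_kriging(EXP, sp, sv, qp)
        assert np.allclose(out.predictions, ok_oracle(EXP, sp, sv, qp), atol=1e-8)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(8)
        sp = rng.uniform(0, 300, (30, 2))
        sv = rng.normal(size=30)
        qp = rng.uniform(0, 300, (7, 2))
        out = ordinary_kriging(EXP, sp, sv, qp, return_weights=True)
        assert np.allclose(out.weights.sum(axis=1), 1.0, atol=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        sp = rng.uniform(0, 100, (12, 2))
        sv = rng.normal(size=12)
        qp = rng.uniform(0, 100, (4, 2))
        a = ordinary_kriging(EXP, sp, sv, qp)
        b = ordinary_kriging(EXP, sp, sv + 100.0, qp)
        assert np.allclose(b.predictions, a.predictions + 100.0, atol=1e-8)
        assert np.allclose(b.variance, a.variance, atol=1e-10)

    def test_duplicates_averaged(self):
        sp = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0]])
        sv = np.array([2.0, 4.0, 5.0])
        with pytest.warns(UserWarning):
            out = ordinary_kriging(EXP, sp, sv, np.array([[0.0, 0.0]]))
        assert np.isfinite(out.predictions[0])


def make_lmc(c12_frac=0.5):
    return CoregionalizationModel(
        "exponential", 50.0,
        nugget_1=0.4, nugget_2=0.2, nugget_12=0.0,
        sill_1=2.0, sill_2=1.5, sill_12=c12_frac * np.sqrt(2.0 * 1.5),
    )


class TestCoKriging:
    def test_psd_invariant_enforced(self):
        with pytest.raises(ValueError):
            CoregionalizationModel("exponential", 50.0, 0.4, 0.2, 0.5,
                                   2.0, 1.5, 0.0)

    def test_decoupled_limit_equals_ok(self):
        lmc = make_lmc(c12_frac=0.0)
        rng = np.random.default_rng(10)
        sp = rng.uniform(0, 100, (15, 2))
        z1 = rng.normal(size=15)
        sp2 = rng.uniform(0, 100, (20, 2))
        z2 = rng.normal(size=20)
        qp = rng.uniform(0, 100, (6, 2))
        ok = ordinary_kriging(VariogramModel("exponential", 0.4, 2.0, 50.0), sp, z1, qp)
        ck = co_kriging(lmc, sp, z1, sp2, z2, qp)
        assert np.allclose(ck.predictions, ok.predictions, atol=1e-8)

    def test_secondary_copy_of_primary_leaves_prediction_unchanged(self):
        lmc = CoregionalizationModel("exponential", 50.0, 0.4, 0.4, 0.4,
                                     2.0, 2.0, 2.0)
        rng = np.random.default_rng(11)
        sp = rng.uniform(0, 100, (12, 2))
        z = rng.normal(size=12)
        qp = rng.uniform(0, 100, (4, 2))
        ok = ordinary_kriging(VariogramModel("exponential", 0.4, 2.0, 50.0), sp, z, qp)
        with pytest.warns(UserWarning):
            ck = co_kriging(lmc, sp, z, sp, z, qp)
        assert np.allclose(ck.predictions, ok.predictions, atol=1e-6)

    def test_weight_constraints(self):
        lmc = make_lmc(0.6)
        rng = np.random.default_rng(12)
        sp = rng.uniform(0, 100, (10, 2))
        z1 = rng.normal(size=10)
        sp2 = rng.uniform(0, 100, (14, 2))
        z2 = rng.normal(size=14)
        qp = rng.uniform(0, 100, (5, 2))
        ck = co_kriging(lmc, sp, z1, sp2, z2, qp, return_weights=True)
        w1, w2 = ck.weights
        assert np.allclose(w1.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(w2.sum(axis=1), 0.0, atol=1e-9)

    def test_correlated_secondary_improves_loo_rmse(self):
        """With a correlated, denser secondary, co-Kriging beats OK in
        leave-one-out RMSE in most repetitions."""
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            pts = rng.uniform(0, 400, (120, 2))
            base = VariogramModel("exponential", 0.1, 1.0, 150.0)
            common = simulate_grf_points(pts, base, seed=seed)
            extra1 = simulate_grf_points(pts, base, seed=1000 + seed)
            z1 = np.sqrt(0.8) * common + np.sqrt(0.2) * extra1
            z2 = common
            prim = rng.permutation(120)[:40]
            p_pts, p_z = pts[prim], z1[prim]
            lmc = fit_lmc(p_pts, p_z, z2[prim], n_lags=8)
            ok_model = lmc.primary
            rms_ok, _ = loo_diagnostics(ok_model, p_pts, p_z)
            # secondary observed everywhere
            eps = []
            for i in range(len(p_pts)):
                keep = np.arange(len(p_pts)) != i
                r = co_kriging(lmc, p_pts[keep], p_z[keep], pts, z2,
                               p_pts[i:i + 1])
                eps.append(p_z[i] - r.predictions[0])
            rms_ck = float(np.sqrt(np.mean(np.square(eps))))
            wins += rms_ck <= rms_ok
        assert wins >= 8, f"CK beat OK in only {wins}/{n_rep} repetitions"


class TestLooDiagnostics:
    def test_rmss_calibrated_under_true_model(self):
        """Data simulated from the assumed model give a standardized LOO
        error near 1 (median over seeds)."""
        model = VariogramModel("exponential", 0.3, 1.0, 120.0)
        rmss_vals = []
        for seed in range(12):
            rng = np.random.default_rng(200 + seed)
            pts = rng.uniform(0, 600, (150, 2))
            z = simulate_grf_points(pts, model, seed=seed)
            _, rmss = loo_diagnostics(model, pts, z)
            rmss_vals.append(rmss)
        assert 0.85 <= np.median(rmss_vals) <= 1.15

    def test_smooth_dense_field_near_zero_rms(self):
        model = VariogramModel("gaussian", 0.0, 1.0, 300.0)
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 200, (60, 2))
        z = simulate_grf_points(pts, model, seed=3)
        rms, _ = loo_diagnostics(model, pts, z)
        assert rms < 0.2 * z.std()

    def test_sill_scaling_halves_rmss(self):
        model = VariogramModel("exponential", 0.3, 1.0, 120.0)
        inflated = VariogramModel("exponential", 1.2, 4.0, 120.0)
        rng = np.random.default_rng(14)
        pts = rng.uniform(0, 600, (60, 2))
        z = simulate_grf_points(pts, model, seed=4)
        rms1, rmss1 = loo_diagnostics(model, pts, z)
        rms4, rmss4 = loo_diagnostics(inflated, pts, z)
        assert np.isclose(rms1, rms4, rtol=1e-10)   # weights unchanged
        assert np.isclose(rmss4, rmss1 / 2.0, rtol=1e-10)
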