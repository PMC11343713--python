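import numpy as np
import pytest
from scipy import stats

from phenofactor.correlations import (
    bvn_cdf,
    build_mixed_correlation,
    build_pearson_correlation,
    estimate_polychoric,
    estimate_polyserial,
    fit_probit_item,
    nearest_psd,
    polychoric_from_counts,
    residualize_continuous,
)
from phenofactor.simulate import simulate_phenome
from .conftest import small_mixed_spec


class TestProbit:
    def test_balanced_binary_threshold_and_truncated_mean(self):
        rng = np.random.default_rng(0)
        x = (rng.standard_normal(50_000) > 0).astype(float)
        fit = fit_probit_item(x)
        assert fit.thresholds[0] == pytest.approx(0.0, abs=0.02)
        # E[latent | x=1] for a prevalence-0.5 item is phi(0)/0.5
        assert fit.expected_resid[x == 1][0] == pytest.approx(0.7979, abs=0.01)
        assert fit.var_xz == pytest.approx(0.6366, abs=0.01)
        assert fit.sigma_x == pytest.approx(0.5, abs=0.005)

    def test_prevalence_point_eight_threshold(self):
        rng = np.random.default_rng(1)
        x = (rng.standard_normal(100_000) > stats.norm.ppf(0.2)).astype(float)
        fit = fit_probit_item(x)
        assert fit.thresholds[0] == pytest.approx(-0.8416, abs=0.02)

    def test_covariate_coefficients_recovered(self):
        rng = np.random.default_rng(2)
        n = 30_000
        z = rng.standard_normal((n, 1))
        latent = 0.5 * z[:, 0] + rng.standard_normal(n)
        codes = np.searchsorted([-0.5, 0.5], latent).astype(float)
        fit = fit_probit_item(codes, z)
        assert fit.coefs[0] == pytest.approx(0.5, abs=0.04)
        assert np.allclose(fit.thresholds, [-0.5, 0.5], atol=0.04)
        obs = ~np.isnan(fit.expected_resid)
        r = np.corrcoef(fit.expected_resid[obs], z[obs, 0])[0, 1]
        assert abs(r) < 0.02  # residual expected values are covariate-free

    def test_rare_categories_collapse(self):
        codes = np.array([0.0] * 100 + [1.0] * 100 + [2.0] * 2)
        fit = fit_probit_item(codes, min_category_count=5)
        assert fit.class_probs.size == 2
        assert fit.collapsed == [(2, 1)]

    def test_constant_item_errors(self):
        with pytest.raises(ValueError):
            fit_probit_item(np.zeros(100))


class TestPolychoric:
    def test_independence_table_gives_zero(self):
        est = polychoric_from_counts(
            np.array([[25.0, 25.0], [25.0, 25.0]]), np.array([0.0]), np.array([0.0])
        )
        assert abs(est.rho) < 1e-6

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.5, 0.8])
    def test_tetrachoric_identity_on_exact_cells(self, rho):
        # p11 = 1/4 + arcsin(rho) / (2*pi) at zero thresholds
        p11 = 0.25 + np.arcsin(rho) / (2 * np.pi)
        cells = np.array([[p11, 0.5 - p11], [0.5 - p11, p11]])
        est = polychoric_from_counts(cells, np.array([0.0]), np.array([0.0]))
        assert est.rho == pytest.approx(rho, abs=1e-3)

    def test_five_level_ordinal_recovery(self):
        rng = np.random.default_rng(3)
        n = 20_000
        cov = np.array([[1.0, 0.7], [0.7, 1.0]])
        latent = rng.multivariate_normal([0, 0], cov, size=n)
        tau = np.array([-1.0, -0.3, 0.4, 1.1])
        a = np.searchsorted(tau, latent[:, 0]).astype(float)
        b = np.searchsorted(tau, latent[:, 1]).astype(float)
        fa, fb = fit_probit_item(a), fit_probit_item(b)
        est = estimate_polychoric(a, b, fa.thresholds, fb.thresholds)
        assert est.rho == pytest.approx(0.70, abs=0.02)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        n = 5_000
        latent = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        a = np.searchsorted([-0.5, 0.5], latent[:, 0]).astype(float)
        b = np.searchsorted([0.0], latent[:, 1]).astype(float)
        fa, fb = fit_probit_item(a), fit_probit_item(b)
        base = estimate_polychoric(a, b, fa.thresholds, fb.thresholds)
        # any strictly increasing relabeling: 0,1,2 -> 0,5,7
        a2 = np.where(a == 1, 5.0, np.where(a == 2, 7.0, 0.0))
        fa2 = fit_probit_item(a2)  # densifies the codes, refits thresholds
        relabeled = estimate_polychoric(fa2.codes, b, fa2.thresholds, fb.thresholds)
        assert relabeled.rho == pytest.approx(base.rho, abs=1e-6)


class TestPolyserial:
    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(5)
        w = rng.standard_normal(20_000)
        codes = (rng.standard_normal(20_000) > 0).astype(float)
        fit = fit_probit_item(codes)
        est = estimate_polyserial(w, codes, fit.thresholds)
        assert abs(est.rho) < 0.02

    def test_attenuation_identity_binary(self):
        # observed Pearson r = rho * phi(0) / sigma_x; polyserial undoes it
        rng = np.random.default_rng(6)
        n = 20_000
        latent = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
        w = latent[:, 0]
        codes = (latent[:, 1] > 0).astype(float)
        pearson = np.corrcoef(w, codes)[0, 1]
        assert pearson == pytest.approx(0.6 * stats.norm.pdf(0) / 0.5, abs=0.02)
        fit = fit_probit_item(codes)
        est = estimate_polyserial(w, codes, fit.thresholds)
        assert est.rho == pytest.approx(0.60, abs=0.02)

    def test_monotone_coarsening_saturates(self):
        rng = np.random.default_rng(7)
        w = rng.standard_normal(5_000)
        codes = np.searchsorted([-1.0, 0.0, 1.0], w).astype(float)
        fit = fit_probit_item(codes)
        est = estimate_polyserial(w, codes, fit.thresholds)
        assert est.rho > 0.99

    def test_zero_variance_continuous_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            estimate_polyserial(
                np.ones(200), np.tile([0.0, 1.0], 100), np.array([0.0])
            )


class TestResidualize:
    def test_no_covariates_centres_and_scales(self):
        rng = np.random.default_rng(8)
        x = 3.0 + 2.0 * rng.standard_normal(1_000)
        r = residualize_continuous(x, None)
        assert abs(r.mean()) < 1e-10
        assert r.std(ddof=1) == pytest.approx(1.0)

    def test_projection_removes_covariate(self):
        rng = np.random.default_rng(9)
        age = rng.standard_normal(2_000)
        item = 2.0 * age + 0.5 * rng.standard_normal(2_000)
        r = residualize_continuous(item, age[:, None])
        assert abs(np.corrcoef(r, age)[0, 1]) < 1e-8

    def test_missing_rows_stay_missing(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(500)
        x[::7] = np.nan
        r = residualize_continuous(x, rng.standard_normal((500, 2)))
        assert np.array_equal(np.isnan(r), np.isnan(x))

    def test_rank_deficient_covariates_named(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal(300)
        with pytest.raises(ValueError, match="collinear"):
            residualize_continuous(
                rng.standard_normal(300), np.column_stack([z, 2.0 * z])
            )


class TestMixedMatrix:
    def test_all_continuous_equals_textbook_partial_correlation(self):
        from .conftest import small_mixed_spec
        from phenofactor.simulate import SimulationSpec

        rng = np.random.default_rng(12)
        n, q = 3_000, 2
        spec = small_mixed_spec(n=n, seed=13)
        spec.item_scales = ["continuous"] * 8
        spec.thresholds = {}
        table, _ = simulate_phenome(spec)
        mc = build_mixed_correlation(table, min_pair_n=10)
        assert (mc.pair_method[~np.eye(8, dtype=bool)] == "pearson").all()
        # oracle: residualize each column on [1, Z], correlate residuals
        design = np.column_stack([np.ones(n), table.covariates])
        H = design @ np.linalg.solve(design.T @ design, design.T)
        resid = table.values - H @ table.values
        oracle = np.corrcoef(resid, rowvar=False)
        off = ~np.eye(8, dtype=bool)
        assert np.max(np.abs(mc.matrix[off] - oracle[off])) < 1e-10

    def test_mixed_recovery_of_latent_structure(self, mixed_table_truth):
        table, truth = mixed_table_truth
        mc = build_mixed_correlation(table)
        err = np.abs(mc.matrix - truth.implied_corr())
        np.fill_diagonal(err, 0.0)
        assert err.max() < 0.03

    def test_matrix_invariants(self, mixed_table_truth):
        table, _ = mixed_table_truth
        mc = build_mixed_correlation(table)
        assert np.allclose(mc.matrix, mc.matrix.T)
        assert np.allclose(np.diag(mc.matrix), 1.0)
        assert (mc.pair_method == mc.pair_method.T).all()
        assert np.abs(mc.matrix).max() <= 1.0

    def test_pearson_variant_treats_codes_numerically(self, mixed_table_truth):
        table, _ = mixed_table_truth
        pc = build_pearson_correlation(table)
        off = ~np.eye(table.p, dtype=bool)
        assert (pc.pair_method[off] == "pearson").all()
        assert np.isfinite(pc.matrix).all()


def test_nearest_psd_repairs_and_preserves_unit_diagonal():
    R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    fixed, repaired = nearest_psd(R)
    assert repaired
    assert np.linalg.eigvalsh(fixed).min() >= 0
    assert np.allclose(np.diag(fixed), 1.0)
    ok, untouched = nearest_psd(np.eye(3))
    assert not untouched


def test_bvn_cdf_against_scipy():
    from scipy.stats import multivariate_normal

    rng = np.random.default_rng(14)
    h = rng.uniform(-2, 2, 20)
    k = rng.uniform(-2, 2, 20)
    for rho in (-0.8, -0.3, 0.5, 0.9):
        mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        expected = np.array([mvn.cdf([hh, kk]) for hh, kk in zip(h, k)])
        assert np.allclose(bvn_cdf(h, k, rho), expected, atol=1e-7)
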