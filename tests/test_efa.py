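import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenofactor.efa import (
    FactorModel,
    efa_fit_stats,
    eigen_diagnostics,
    minres_extract,
    pca_components,
    threshold_pattern,
    varimax_rotate,
)
from phenofactor.evaluation import align_factors
from phenofactor.simulate import default_spec, simulate_phenome


def sparse_loadings(p=12, t=3, seed=0):
    rng = np.random.default_rng(seed)
    lam = np.zeros((p, t))
    mags = rng.uniform(0.4, 0.85, p)
    for j in range(p):
        lam[j, j % t] = mags[j]
    return lam


def implied(lam):
    R = lam @ lam.T
    np.fill_diagonal(R, 1.0)
    return R


class TestEigenDiagnostics:
    def test_identity_matrix(self):
        d = eigen_diagnostics(np.eye(6), n=500, n_null_reps=20, seed=1)
        assert np.allclose(d.eigenvalues, 1.0)
        assert d.parallel_count == 0
        assert d.kaiser_count == 0

    def test_equicorrelated_closed_form(self):
        R = np.full((4, 4), 0.5)
        np.fill_diagonal(R, 1.0)
        d = eigen_diagnostics(R, n=1_000, n_null_reps=10, seed=2)
        assert np.allclose(d.eigenvalues, [2.5, 0.5, 0.5, 0.5])
        assert d.eigenvalues.sum() == pytest.approx(4.0, abs=1e-8)

    def test_parallel_analysis_detects_factors(self):
        lam = sparse_loadings(p=20, t=5, seed=3)
        hits = 0
        for seed in range(5):
            spec_R = implied(lam)
            # sample correlation at n=20000 from the implied model
            rng = np.random.default_rng(seed)
            X = rng.multivariate_normal(np.zeros(20), spec_R, size=20_000)
            d = eigen_diagnostics(np.corrcoef(X, rowvar=False), n=20_000,
                                  n_null_reps=30, seed=seed)
            hits += d.parallel_count >= 5
        assert hits >= 5 * 0.95

    def test_asymmetric_input_rejected(self):
        M = np.eye(3)
        M[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            eigen_diagnostics(M, n=100)


class TestMinres:
    def test_triad_closed_form(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.72
        R[0, 2] = R[2, 0] = 0.63
        R[1, 2] = R[2, 1] = 0.56
        m = minres_extract(R, 1)
        # lambda_1 = sqrt(r12 * r13 / r23) etc.
        assert np.allclose(np.abs(m.loadings.ravel()), [0.9, 0.8, 0.7], atol=1e-5)
        assert np.allclose(m.uniquenesses, [0.19, 0.36, 0.51], atol=1e-5)
        assert not m.heywood_flags.any()

    def test_perfect_fit_fixed_point(self):
        lam = sparse_loadings(seed=4)
        m = minres_extract(implied(lam), 3)
        resid = implied(lam) - m.implied_corr()
        off = resid[~np.eye(12, dtype=bool)]
        assert np.sum(off**2) < 1e-10
        _, _, congruence = align_factors(m.loadings, lam)
        assert congruence.min() > 1.0 - 1e-6

    def test_heywood_triad_flagged(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.9
        R[0, 2] = R[2, 0] = 0.9
        R[1, 2] = R[2, 1] = 0.5
        m = minres_extract(R, 1)
        assert m.heywood_flags[0]

    def test_item_order_invariance_up_to_alignment(self):
        lam = sparse_loadings(seed=5)
        R = implied(lam)
        perm = np.random.default_rng(6).permutation(12)
        m1 = minres_extract(R, 3)
        m2 = minres_extract(R[np.ix_(perm, perm)], 3)
        _, _, congruence = align_factors(m2.loadings, lam[perm])
        assert congruence.min() > 1.0 - 1e-6


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        lam = sparse_loadings(seed=7)
        model = FactorModel(lam, 1 - (lam**2).sum(1), [f"i{j}" for j in range(12)])
        rot, R = varimax_rotate(model)
        _, _, congruence = align_factors(rot.loadings, lam)
        assert congruence.min() > 1.0 - 1e-8
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-8)

    def test_undoes_thirty_degree_rotation(self):
        lam = np.zeros((8, 2))
        lam[:4, 0] = [0.8, 0.7, 0.6, 0.75]
        lam[4:, 1] = [0.65, 0.7, 0.8, 0.6]
        th = np.deg2rad(30.0)
        G = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        model = FactorModel(lam @ G, 1 - (lam**2).sum(1), [f"i{j}" for j in range(8)])
        rot, R = varimax_rotate(model)
        _, _, congruence = align_factors(rot.loadings, lam)
        assert congruence.min() > 0.999
        assert np.allclose(rot.loadings, model.loadings @ R)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rotation_preserves_communalities_and_fit(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(-0.7, 0.7, (9, 3))
        lam *= 0.95 / max(1.0, np.sqrt((lam**2).sum(1)).max())
        model = FactorModel(lam, 1 - (lam**2).sum(1), [f"i{j}" for j in range(9)])
        rot, _ = varimax_rotate(model)
        assert np.allclose(
            (rot.loadings**2).sum(1), (lam**2).sum(1), atol=1e-10
        )
        assert np.allclose(
            rot.loadings @ rot.loadings.T, lam @ lam.T, atol=1e-10
        )


class TestFitStatsAndPCA:
    def test_perfect_fit_zero_rms(self):
        lam = sparse_loadings(seed=8)
        m = minres_extract(implied(lam), 3)
        stats = efa_fit_stats(implied(lam), m)
        assert stats["rms_residual"] < 1e-6

    def test_variance_explained_arithmetic(self):
        lam = np.full((10, 1), 0.5)
        model = FactorModel(lam, 1 - (lam**2).sum(1), [f"i{j}" for j in range(10)])
        stats = efa_fit_stats(implied(lam), model)
        assert stats["variance_explained"] == pytest.approx(0.25)

    def test_equicorrelated_first_component_uniform(self):
        R = np.full((5, 5), 0.4)
        np.fill_diagonal(R, 1.0)
        comp = pca_components(R, 1)
        direction = comp[:, 0] / np.linalg.norm(comp[:, 0])
        assert np.allclose(np.abs(direction), 1 / np.sqrt(5), atol=1e-10)

    def test_pca_explains_at_least_fa_variance(self):
        lam = sparse_loadings(p=15, t=4, seed=9)
        R = implied(lam)
        fa = minres_extract(R, 4)
        pca = pca_components(R, 4)
        assert np.sum(pca**2) >= np.sum(fa.loadings**2) - 1e-10

    def test_pca_loadings_denser_than_varimax(self):
        # with sparse truth, rotated FA loadings concentrate; PCA spreads
        spec = default_spec(n_individuals=5_000)
        _, truth = simulate_phenome(spec)
        R = truth.implied_corr()
        fa, _ = varimax_rotate(minres_extract(R, 5))
        pca = pca_components(R, 5)
        assert (np.abs(pca) > 0.1).sum() > (np.abs(fa.loadings) > 0.1).sum()


class TestThresholdPattern:
    def test_boundary_is_strict(self):
        lam = np.array([[0.10, 0.0], [0.5, 0.0], [0.0, 0.4], [0.3, 0.2]])
        model = FactorModel(lam, 1 - (lam**2).sum(1), list("abcd"))
        with pytest.warns(UserWarning, match="fewer than 3"):
            pattern, dropped = threshold_pattern(model, cutoff=0.1)
        assert not pattern[0, 0]  # exactly 0.1 excluded
        assert dropped == [0]

    def test_all_above_cutoff_fully_free(self):
        lam = np.full((6, 2), 0.4)
        model = FactorModel(lam, np.full(6, 0.5), list("abcdef"))
        pattern, dropped = threshold_pattern(model, cutoff=0.1)
        assert pattern.all() and dropped == []

    def test_recovers_true_sparsity_at_scale(self, default_pipeline):
        truth_pattern = default_pipeline.truth.loadings[default_pipeline.kept_items] != 0
        est = default_pipeline.pattern
        perm = default_pipeline.recovery.permutation
        est_aligned = est[:, perm[: truth_pattern.shape[1]]]
        false_free = (est_aligned & ~truth_pattern).mean()
        assert false_free <= 0.05
        assert (truth_pattern & ~est_aligned).mean() == 0.0
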