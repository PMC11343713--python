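import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phenofactor.correlations import ProbitFit
from phenofactor.efa import FactorModel
from phenofactor.scoring import (
    BARTLETT,
    THOMSON_THURSTONE,
    adjust_categorical,
    build_scoring_coefficients,
    pattern_coefficients,
    reliability_and_completeness,
    score_individuals,
    score_weights,
)


def two_item_model():
    lam = np.array([[0.8], [0.6]])
    psi = np.array([0.36, 0.64])
    return lam, psi


def balanced_binary_fit(expected_resid=None, n=4):
    """Analytic probit summary of a prevalence-0.5 binary item."""
    phi0 = stats.norm.pdf(0.0)
    ev = expected_resid if expected_resid is not None else np.zeros(n)
    return ProbitFit(
        thresholds=np.array([0.0]),
        coefs=np.zeros(0),
        sigma_x=0.5,
        class_probs=np.array([0.5, 0.5]),
        expected_resid=ev,
        offsets=np.zeros(n),
        var_xz=phi0**2 / 0.25,  # two-point distribution ±phi(0)/0.5
        codes=np.zeros(n),
    )


class TestCoefficients:
    def test_single_item_scalar_algebra(self):
        lam = np.array([[0.8]])
        psi = np.array([0.36])
        a_b = pattern_coefficients(BARTLETT, lam, psi, np.array([0]))
        a_tt = pattern_coefficients(THOMSON_THURSTONE, lam, psi, np.array([0]))
        assert a_b[0, 0] == pytest.approx(1.25, abs=1e-10)
        # lambda^2 + psi = 1 makes the regression coefficient exactly lambda
        assert a_tt[0, 0] == pytest.approx(0.8, abs=1e-10)

    def test_two_item_vectors(self):
        lam, psi = two_item_model()
        a_b = pattern_coefficients(BARTLETT, lam, psi, np.arange(2))
        a_tt = pattern_coefficients(THOMSON_THURSTONE, lam, psi, np.arange(2))
        assert np.allclose(a_b.ravel(), [0.9495, 0.4006], atol=1e-4)
        assert np.allclose(a_tt.ravel(), [0.6653, 0.2806], atol=1e-4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bartlett_conditional_unbiasedness_identity(self, seed):
        rng = np.random.default_rng(seed)
        p, t = 10, 3
        lam = np.zeros((p, t))
        for j in range(p):
            lam[j, j % t] = rng.uniform(0.3, 0.9)
        lam[rng.integers(p), (rng.integers(t))] = rng.uniform(-0.3, 0.3)
        lam *= 0.95 / max(1.0, np.sqrt((lam**2).sum(1)).max())
        psi = 1.0 - (lam**2).sum(1)
        observed = np.flatnonzero(rng.random(p) < 0.7)
        if observed.size == 0:
            observed = np.arange(p)
        A = pattern_coefficients(BARTLETT, lam, psi, observed)
        ok = np.isfinite(A).all(axis=0)
        if ok.any():
            prod = A[:, ok].T @ lam[observed][:, ok]
            assert np.allclose(prod, np.eye(int(ok.sum())), atol=1e-8)

    def test_thomson_thurstone_is_shrunken_bartlett(self):
        lam, psi = two_item_model()
        c = float((lam**2 / psi[:, None]).sum())
        a_b = pattern_coefficients(BARTLETT, lam, psi, np.arange(2))
        a_tt = pattern_coefficients(THOMSON_THURSTONE, lam, psi, np.arange(2))
        assert np.allclose(a_tt, a_b * c / (1 + c), atol=1e-12)

    def test_unscorable_factor_marked_nan(self):
        lam = np.array([[0.8, 0.0], [0.0, 0.7], [0.0, 0.6]])
        psi = 1.0 - (lam**2).sum(1)
        A = pattern_coefficients(BARTLETT, lam, psi, np.array([1, 2]))
        assert np.isnan(A[:, 0]).all()
        assert np.isfinite(A[:, 1]).all()


class TestCategoricalAdjustment:
    def test_loading_adjustment_balanced_binary(self):
        model = FactorModel(
            np.array([[0.5]]), np.array([0.75]), ["b1"], provenance="cfa"
        )
        fit = balanced_binary_fit()
        lam_star, psi_star = adjust_categorical(model, {0: fit})
        # sqrt(var) * sum phi / sigma = 0.79788 * 0.79788
        assert lam_star[0, 0] == pytest.approx(0.5 * 0.63662, abs=1e-4)
        assert psi_star[0] == pytest.approx(0.5353, abs=1e-4)

    def test_continuous_rows_untouched(self):
        lam = np.array([[0.5], [0.6]])
        model = FactorModel(lam, np.array([0.75, 0.64]), ["b1", "c1"],
                            provenance="cfa")
        lam_star, psi_star = adjust_categorical(model, {0: balanced_binary_fit()})
        assert lam_star[1, 0] == 0.6
        assert psi_star[1] == 0.64

    def test_constant_item_rejected(self):
        model = FactorModel(np.array([[0.5]]), np.array([0.75]), ["b1"])
        fit = balanced_binary_fit()
        fit.sigma_x = 0.0
        with pytest.raises(ValueError, match="sigma_x"):
            adjust_categorical(model, {0: fit})


class TestWeights:
    def test_two_item_weight_arithmetic(self):
        lam, psi = two_item_model()
        A = pattern_coefficients(BARTLETT, lam, psi, np.arange(2))
        S = lam @ lam.T + np.diag(psi)
        w = score_weights(A, S)
        assert (A.T @ S @ A)[0, 0] == pytest.approx(1.4273, abs=1e-4)
        assert w[0] == pytest.approx(0.7006, abs=1e-4)

    def test_bartlett_weight_identity_under_model(self):
        lam, psi = two_item_model()
        A = pattern_coefficients(BARTLETT, lam, psi, np.arange(2))
        S = lam @ lam.T + np.diag(psi)
        c = float((lam**2 / psi[:, None]).sum())
        assert score_weights(A, S)[0] == pytest.approx(1 / (1 + 1 / c), abs=1e-10)

    def test_weight_monotone_in_observed_items(self):
        lam = np.array([[0.8], [0.6], [0.5]])
        psi = 1.0 - (lam**2).sum(1)
        S = lam @ lam.T + np.diag(psi)
        weights = []
        for obs in (np.array([0]), np.array([0, 1]), np.array([0, 1, 2])):
            A = pattern_coefficients(BARTLETT, lam, psi, obs)
            weights.append(score_weights(A, S[np.ix_(obs, obs)])[0])
        assert weights[0] <= weights[1] <= weights[2]

    def test_nonpositive_variance_rejected(self):
        A = np.array([[1.0]])
        with pytest.raises(ValueError, match="non-positive"):
            score_weights(A, np.array([[-0.5]]))


class TestReliability:
    def test_single_item_closed_form(self):
        lam = np.array([[0.8]])
        psi = np.array([0.36])
        rel, comp, inc = reliability_and_completeness(lam, psi, np.array([0]))
        c = 0.64 / 0.36
        assert rel[0] == pytest.approx(np.sqrt(c / (1 + c)), abs=1e-10)
        assert rel[0] == pytest.approx(0.8, abs=1e-10)

    def test_two_item_closed_form(self):
        lam, psi = two_item_model()
        rel, comp, inc = reliability_and_completeness(lam, psi, np.arange(2))
        assert rel[0] == pytest.approx(np.sqrt(2.3403 / 3.3403), abs=1e-4)
        assert rel[0] == pytest.approx(0.8370, abs=1e-4)

    def test_no_missingness_full_completeness(self):
        lam, psi = two_item_model()
        _, comp, inc = reliability_and_completeness(lam, psi, np.arange(2))
        assert comp[0] == pytest.approx(1.0, abs=1e-10)
        assert inc[0]

    def test_completeness_drops_with_missing_items(self):
        lam = np.array([[0.8], [0.6], [0.5]])
        psi = 1.0 - (lam**2).sum(1)
        _, comp_full, _ = reliability_and_completeness(lam, psi, np.arange(3))
        _, comp_one, _ = reliability_and_completeness(lam, psi, np.array([2]))
        assert comp_one[0] < comp_full[0]


class TestScoring:
    def make_set(self, method=BARTLETT):
        lam = np.array([[0.8]])
        psi = np.array([0.36])
        model = FactorModel(lam, psi, ["c1"], provenance="cfa")
        values = np.array([[1.0], [np.nan], [0.5]])
        return build_scoring_coefficients(model, values, method=method), values

    def test_single_item_score_is_coefficient_times_value(self):
        coef, values = self.make_set()
        # degenerate sample covariance: supply the model-implied one
        coef.sample_cov = np.array([[1.0]])
        sc = score_individuals(values, coef)
        assert sc.scores[0, 0] == pytest.approx(1.25, abs=1e-10)

    def test_all_loaded_items_missing_gives_no_score(self):
        coef, values = self.make_set()
        coef.sample_cov = np.array([[1.0]])
        sc = score_individuals(values, coef)
        assert np.isnan(sc.scores[1, 0])
        assert not sc.included[1, 0]

    def test_empirical_reliability_and_slope_and_weight(self):
        rng = np.random.default_rng(42)
        n = 20_000
        lam = np.zeros((8, 2))
        lam[:4, 0] = [0.8, 0.7, 0.6, 0.5]
        lam[4:, 1] = [0.75, 0.65, 0.6, 0.55]
        psi = 1.0 - (lam**2).sum(1)
        F = rng.standard_normal((n, 2))
        X = F @ lam.T + rng.standard_normal((n, 8)) * np.sqrt(psi)
        X[: n // 2, 3] = np.nan  # one structured pattern
        model = FactorModel(lam, psi, [f"i{j}" for j in range(8)], provenance="cfa")
        coef = build_scoring_coefficients(model, X, method=BARTLETT)
        sc = score_individuals(X, coef)
        for rows in (slice(None, n // 2), slice(n // 2, None)):
            r_emp = np.corrcoef(sc.scores[rows, 0], F[rows, 0])[0, 1]
            assert r_emp == pytest.approx(sc.reliability[rows, 0][0], abs=0.02)
            slope = np.polyfit(F[rows, 0], sc.scores[rows, 0], 1)[0]
            assert slope == pytest.approx(1.0, abs=0.02)
            var_ratio = np.var(sc.scores[rows, 0]) * sc.weights[rows, 0][0]
            assert var_ratio == pytest.approx(1.0, rel=0.05)
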