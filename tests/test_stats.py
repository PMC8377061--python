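"""Derived genetic statistics and likelihood-based model comparison."""

from types import SimpleNamespace

import numpy as np
import pytest

import gsemkit as gk
from gsemkit.exceptions import DatasetMismatchError
from gsemkit.stats import correlation_matrix


def _fit_from_loadings(spec, La, Le, vcov=None):
    theta = spec.pack(gk.LoadingMatrices(lambda_a=La, lambda_e=Le))
    k = spec.k
    return gk.FitResult(spec=spec, estimates=theta, loglik=-100.0, n_used=500,
                        k=k, param_vcov=vcov if vcov is not None else np.eye(k) * 1e-4,
                        converged=True, n_restarts_agreeing=1, engine="rotation")


@pytest.fixture
def chol2_fit():
    """Two-trait saturated fit with genetic loadings (0.8,0)/(0.4,0.3)."""
    spec = gk.from_preset("cholesky", ["a", "b"])
    La = np.array([[0.8, 0.0], [0.4, 0.3]])
    Le = np.array([[0.6, 0.0], [0.1, 0.7]])
    return _fit_from_loadings(spec, La, Le)


class TestComponents:
    def test_hand_evaluated_product(self, chol2_fit):
        comp = gk.components_from_fit(chol2_fit)
        np.testing.assert_allclose(
            comp.sigma_g, [[0.64, 0.32], [0.32, 0.25]], atol=1e-12)
        np.testing.assert_allclose(
            comp.sigma_p, comp.sigma_g + comp.sigma_e, atol=0)

    def test_zero_and_identity_loadings(self):
        spec = gk.from_preset("cholesky", ["a", "b"])
        z = _fit_from_loadings(spec, np.zeros((2, 2)), np.eye(2))
        np.testing.assert_array_equal(
            gk.components_from_fit(z).sigma_g, np.zeros((2, 2)))
        i = _fit_from_loadings(spec, np.eye(2), np.eye(2))
        np.testing.assert_array_equal(
            gk.components_from_fit(i).sigma_g, np.eye(2))


class TestGeneticCorrelations:
    def test_hand_evaluated_rg(self, chol2_fit):
        rg, rg_se = gk.genetic_correlations(chol2_fit)
        # 0.32 / (0.8 * 0.5) = 0.8
        assert rg.loc["a", "b"] == pytest.approx(0.8, abs=1e-12)
        assert rg_se.loc["a", "b"] > 0

    def test_zero_genetic_covariance_gives_zero_rg(self):
        spec = gk.from_preset("cholesky", ["a", "b"])
        fit = _fit_from_loadings(spec, np.diag([0.7, 0.5]), np.eye(2))
        rg, _ = gk.genetic_correlations(fit)
        assert rg.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_common_factor_gives_unit_rg(self):
        spec = gk.from_preset("ipc", ["a", "b", "c"])
        La = np.zeros((3, 4))
        La[:, 0] = [0.5, 0.6, 0.7]
        fit = _fit_from_loadings(spec, La, np.eye(3))
        rg, _ = gk.genetic_correlations(fit)
        off = rg.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-10)

    def test_zero_genetic_variance_pair_reported_missing(self):
        spec = gk.from_preset("cholesky", ["a", "b"])
        fit = _fit_from_loadings(spec, np.diag([0.7, 0.0]), np.eye(2))
        rg, _ = gk.genetic_correlations(fit)
        assert np.isnan(rg.loc["a", "b"])

    def test_rg_from_psd_sigma_g_is_psd(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            L = rng.normal(size=(5, 5))
            R = correlation_matrix(L @ L.T + 1e-6 * np.eye(5))
            assert np.linalg.eigvalsh(R).min() >= -1e-8


class TestFactorialCoheritability:
    def test_single_factor_gives_unit_f2(self):
        spec = gk.from_preset("ipc", ["a", "b", "c"])
        La = np.zeros((3, 4))
        La[:, 0] = [0.5, 0.6, 0.7]
        f2, _ = gk.factorial_coheritability(_fit_from_loadings(spec, La, np.eye(3)))
        np.testing.assert_allclose(f2["AC"], 1.0, atol=1e-12)

    def test_equal_contributions_split_half(self):
        spec = gk.from_preset("ipc", ["a", "b", "c"])
        La = np.zeros((3, 4))
        La[:, 0] = 0.4
        La[np.arange(3), np.arange(1, 4)] = 0.4
        f2, _ = gk.factorial_coheritability(_fit_from_loadings(spec, La, np.eye(3)))
        np.testing.assert_allclose(f2["AC"], 0.5, atol=1e-12)

    def test_hand_evaluated_common_share(self):
        # common loading^2 = 0.27, specific^2 = 0.03 -> f2_common = 0.9
        spec = gk.from_preset("ipc", ["a", "b", "c"])
        La = np.zeros((3, 4))
        La[:, 0] = np.sqrt([0.27, 0.3, 0.3])
        La[0, 1] = np.sqrt(0.03)
        f2, _ = gk.factorial_coheritability(_fit_from_loadings(spec, La, np.eye(3)))
        assert f2.loc["a", "AC"] == pytest.approx(0.9, abs=1e-12)

    def test_f2_sums_to_one_per_trait(self, chol2_fit):
        f2, _ = gk.factorial_coheritability(chol2_fit)
        np.testing.assert_allclose(f2.sum(axis=1), 1.0, atol=1e-10)


class TestBivariateHeritability:
    def test_hand_evaluated_ratio_and_se(self, chol2_fit):
        obs = np.array([[1.0, 0.40], [0.40, 1.0]])
        h2, h2_se = gk.bivariate_heritability(chol2_fit, obs)
        assert h2.loc["a", "b"] == pytest.approx(0.32 / 0.40, abs=1e-12)
        # SE contract: SE(sigma_g12) / sigma_p12
        def gcov(theta):
            La = chol2_fit.spec.loadings(theta).lambda_a
            return np.array([(La @ La.T)[0, 1]])
        from gsemkit.stats import _delta_se
        se_g = _delta_se(chol2_fit, gcov)[0]
        assert h2_se.loc["a", "b"] == pytest.approx(se_g / 0.40, rel=1e-9)

    def test_equal_covariances_give_unit_ratio(self, chol2_fit):
        obs = np.array([[1.0, 0.32], [0.32, 1.0]])
        h2, _ = gk.bivariate_heritability(chol2_fit, obs)
        assert h2.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_genetic_covariance_gives_zero(self):
        spec = gk.from_preset("cholesky", ["a", "b"])
        fit = _fit_from_loadings(spec, np.diag([0.7, 0.5]), np.eye(2))
        h2, _ = gk.bivariate_heritability(fit, np.array([[1.0, 0.4], [0.4, 1.0]]))
        assert h2.loc["a", "b"] == pytest.approx(0.0)

    def test_unstable_phenotypic_covariance_reported_missing(self, chol2_fit):
        obs = np.array([[1.0, 1e-12], [1e-12, 1.0]])
        h2, _ = gk.bivariate_heritability(chol2_fit, obs)
        assert np.isnan(h2.loc["a", "b"])


class TestInformationCriteria:
    def test_zero_parameters_collapse_to_deviance(self):
        aic, bic = gk.information_criteria(-123.4, 0, 50)
        assert aic == bic == pytest.approx(246.8)

    def test_aic_minus_deviance_is_twice_k(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            ll = rng.normal(-5000, 100)
            k = int(rng.integers(1, 40))
            aic, _ = gk.information_criteria(ll, k, 1000)
            assert aic - (-2 * ll) == pytest.approx(2 * k, abs=1e-9)

    def test_bic_uses_individuals_in_sample(self):
        _, bic = gk.information_criteria(-8909.53, 30, 6453)
        assert bic == pytest.approx(17819.06 + 30 * np.log(6453), abs=1e-9)


class TestCompareModels:
    def _m(self, loglik, k, name):
        return SimpleNamespace(loglik=loglik, k=k,
                               spec=SimpleNamespace(name=name))

    def test_model_against_itself(self):
        sat = self._m(-100.0, 10, "sat")
        out = gk.compare_models({"sat": sat}, sat, 200)
        assert out.loc["sat", "delta_chi2"] == 0.0
        assert out.loc["sat", "delta_df"] == 0

    def test_lowest_bic_selected(self):
        sat = self._m(-100.0, 10, "sat")
        mid = self._m(-101.0, 6, "mid")
        out = gk.compare_models({"sat": sat, "mid": mid}, sat, 500)
        assert bool(out.loc["mid", "selected"])
        assert not bool(out.loc["sat", "selected"])

    def test_negative_deviance_beyond_tolerance_raises(self):
        sat = self._m(-100.0, 10, "sat")
        better = self._m(-99.0, 6, "impossible")
        with pytest.raises(DatasetMismatchError):
            gk.compare_models({"m": better}, sat, 100)

    def test_tiny_negative_deviance_clamped(self):
        sat = self._m(-100.0, 10, "sat")
        jitter = self._m(-100.0 + 2e-6, 6, "jitter")
        out = gk.compare_models({"jitter": jitter}, sat, 100)
        assert out.loc["jitter", "delta_chi2"] == 0.0
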