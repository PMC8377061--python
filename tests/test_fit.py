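"""Likelihood engines, ML fitting, observed information and Wald tests."""

import numpy as np
import pytest
from scipy import stats as sps

import gsemkit as gk
from gsemkit.fit import _observed_information


def _identity_dataset(y, traits):
    n = y.shape[0]
    ids = [(f"F{i}", f"I{i}") for i in range(n)]
    grm = gk.GRMatrix(ids=ids, values=np.eye(n))
    return gk.AnalysisDataset(y=y, grm=grm, trait_names=traits,
                              n_union=n, n_complete=n)


class TestLoglik:
    def test_univariate_identity_grm_reduces_to_iid_normal(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(50, 1))
        ds = _identity_dataset(y, ["y"])
        spec = gk.from_preset("cholesky", ["y"])
        a, e = 0.6, 0.9
        expected = sps.norm.logpdf(y, scale=np.sqrt(a**2 + e**2)).sum()
        for engine in ("rotation", "direct"):
            got = gk.loglik(spec, np.array([a, e]), ds, engine=engine)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_engines_agree_on_complete_data(self, small_study):
        _, _, _, ds = small_study
        sub = gk.AnalysisDataset(ds.y[:60], ds.grm.subset(np.arange(60)),
                                 ds.trait_names, 60, 60)
        spec = gk.from_preset("cholesky", ds.trait_names)
        rng = np.random.default_rng(1)
        for _ in range(5):
            theta = rng.normal(scale=0.7, size=spec.k)
            lr = gk.loglik(spec, theta, sub, engine="rotation")
            ld = gk.loglik(spec, theta, sub, engine="direct")
            assert lr == pytest.approx(ld, abs=1e-6)

    def test_direct_engine_matches_hand_assembled_kronecker(self, toy_grm):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(4, 2))
        ds = gk.AnalysisDataset(y=y, grm=toy_grm, trait_names=["a", "b"],
                                n_union=4, n_complete=4)
        spec = gk.from_preset("cholesky", ["a", "b"])
        theta = np.array([0.7, 0.3, 0.5, 0.9, -0.2, 0.8])
        lm = spec.loadings(theta)
        Sg = lm.lambda_a @ lm.lambda_a.T
        Se = lm.lambda_e @ lm.lambda_e.T
        # brute-force 8x8 covariance, individual-major ordering
        C = np.kron(toy_grm.values, Sg) + np.kron(np.eye(4), Se)
        expected = sps.multivariate_normal(mean=np.zeros(8), cov=C).logpdf(
            y.ravel())
        got = gk.loglik(spec, theta, ds, engine="direct")
        assert got == pytest.approx(expected, abs=1e-8)

    def test_direct_engine_handles_missing_entries(self, toy_grm):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(4, 2))
        y[1, 0] = np.nan
        ds = gk.AnalysisDataset(y=y, grm=toy_grm, trait_names=["a", "b"],
                                n_union=4, n_complete=3)
        spec = gk.from_preset("cholesky", ["a", "b"])
        theta = np.array([0.7, 0.3, 0.5, 0.9, -0.2, 0.8])
        lm = spec.loadings(theta)
        C = (np.kron(toy_grm.values, lm.lambda_a @ lm.lambda_a.T)
             + np.kron(np.eye(4), lm.lambda_e @ lm.lambda_e.T))
        obs = np.where(~np.isnan(y.ravel()))[0]
        expected = sps.multivariate_normal(
            mean=np.zeros(7), cov=C[np.ix_(obs, obs)]).logpdf(y.ravel()[obs])
        assert gk.loglik(spec, theta, ds, engine="direct") == pytest.approx(
            expected, abs=1e-8)

    def test_singular_implied_covariance_returns_neg_inf(self):
        y = np.zeros((5, 2))
        y[:, 0] = np.arange(5.0)
        y[:, 1] = np.arange(5.0)
        ds = _identity_dataset(y, ["a", "b"])
        spec = gk.from_preset("cholesky", ["a", "b"])
        theta = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])  # Se singular
        assert gk.loglik(spec, theta, ds, engine="rotation") == -np.inf


class TestFitML:
    def test_univariate_recovery_within_two_se(self):
        # truth h2 = 0.4 on a genotype-derived GRM
        scen = gk.Scenario(trait_names=["y"],
                           lambda_a=np.array([[np.sqrt(0.4)]]),
                           lambda_e=np.array([[np.sqrt(0.6)]]),
                           n=800, m=2000, seed=7, name="uni")
        grm, pheno = gk.simulate_study(scen, route="genotype")
        ds = gk.align(pheno, grm, mode="complete", require_transformed=False)
        fit = gk.fit_ml(gk.from_preset("cholesky", ["y"]), ds,
                        n_starts=3, seed=1)
        h2, se = gk.snp_heritability(fit)
        assert fit.converged
        assert abs(h2["y"] - 0.4) < 2 * se["y"]

    def test_loglik_monotone_in_nesting(self, small_study):
        _, _, _, ds = small_study
        lls = {}
        for name in ("cholesky", "ipc", "ip"):
            spec = gk.from_preset(name, ds.trait_names)
            lls[name] = gk.fit_ml(spec, ds, n_starts=3, seed=0,
                                  compute_vcov=False).loglik
        assert lls["cholesky"] >= lls["ipc"] - 1e-4
        assert lls["ipc"] >= lls["ip"] - 1e-4

    def test_identity_grm_flags_unidentified_information(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(120, 1))
        ds = _identity_dataset(y, ["y"])
        fit = gk.fit_ml(gk.from_preset("cholesky", ["y"]), ds,
                        n_starts=2, seed=0)
        # no relatedness contrast: genetic vs residual split unidentified
        assert fit.param_vcov is None
        assert any("information" in m for m in fit.messages)

    def test_rotation_reduces_to_complete_cases(self, small_study):
        _, _, _, ds = small_study
        y = ds.y.copy()
        y[0, 0] = np.nan
        missing = gk.AnalysisDataset(y, ds.grm, ds.trait_names,
                                     ds.n, ds.n - 1)
        fit = gk.fit_ml(gk.from_preset("cholesky", ds.trait_names), missing,
                        n_starts=1, seed=0, compute_vcov=False)
        assert fit.n_used == ds.n - 1
        assert any("complete cases" in m for m in fit.messages)


class TestObservedInformation:
    def test_quadratic_recovers_constant_hessian(self):
        H = np.array([[2.0, 0.5], [0.5, 3.0]])

        def ll(theta):
            return -0.5 * theta @ H @ theta

        info = _observed_information(ll, np.array([0.3, -0.2]))
        np.testing.assert_allclose(info, H, atol=1e-6)
        np.testing.assert_array_equal(info, info.T)

    def test_univariate_iid_matches_analytic_information(self):
        rng = np.random.default_rng(4)
        n = 300
        y = rng.normal(scale=1.2, size=(n, 1))
        ds = _identity_dataset(y, ["y"])
        spec = gk.from_preset("cholesky", ["y"])
        a, e = 0.8, 0.9
        s = float(np.sum(y**2))
        var = a**2 + e**2
        # closed-form Hessian of the iid normal loglik in (a, e)
        base = -n / var + s / var**2
        curv = 2 * n / var**2 - 4 * s / var**3
        H = np.array([[base + a * a * curv, a * e * curv],
                      [a * e * curv, base + e * e * curv]])
        info = gk.observed_information(spec, np.array([a, e]), ds)
        np.testing.assert_allclose(info, -H, rtol=1e-3)


class TestWald:
    def _fit(self, estimates, vcov):
        spec = gk.from_preset("cholesky", ["y"])
        return gk.FitResult(spec=spec, estimates=np.asarray(estimates),
                            loglik=0.0, n_used=10, k=2, param_vcov=vcov,
                            converged=True, n_restarts_agreeing=1,
                            engine="rotation")

    def test_zero_estimate_unit_se_gives_p_one(self):
        w = gk.wald_tests(self._fit([0.0, 1.0], np.eye(2)))
        assert w.loc[0, "p"] == pytest.approx(1.0)

    def test_critical_value_gives_p_005(self):
        w = gk.wald_tests(self._fit([1.959964, 1.0], np.eye(2)))
        assert w.loc[0, "p"] == pytest.approx(0.05, abs=1e-6)
        assert bool(w.loc[0, "sig_nominal"])
        assert not bool(w.loc[0, "sig_experimentwide"])

    def test_missing_se_yields_na_row_without_exception(self):
        w = gk.wald_tests(self._fit([0.5, 1.0], None))
        assert np.isnan(w["se"]).all() and np.isnan(w["p"]).all()

    def test_experimentwide_threshold_flag(self):
        w = gk.wald_tests(self._fit([3.0, 1.0], np.eye(2)))
        assert bool(w.loc[0, "sig_experimentwide"])
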