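"""Derived quantities from a fitted model, and likelihood-based model comparison.

From fitted loadings the module derives:

* genetic / residual correlations, ``r = cov_12 / sqrt(var_1 var_2)`` applied
  to the genetic (or residual) covariance implied by the loadings;
* per-trait SNP heritability, ``h2 = sigma_g_tt / (sigma_g_tt + sigma_e_tt)``;
* factorial co-heritabilities, ``f2(i, t)``: the share of trait ``t``'s total
  genetic variance contributed by genetic factor ``i`` (shares sum to 1 over
  factors per trait);
* bivariate heritabilities, ``h2_biv = sigma_g_12 / sigma_p_12`` with the
  phenotypic covariance taken from the observed (rank-transformed) data.

Standard errors use the delta method with numerical Jacobians of each
statistic with respect to the free parameters, sandwiched with the fitted
parameter covariance.  Model comparison uses AIC/BIC and likelihood-ratio
tests against the saturated (Cholesky/Cholesky) model with naive df counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DatasetMismatchError, NumericalDegeneracyError
from .fit import FitResult

__all__ = [
    "GeneticComponents",
    "DerivedStats",
    "components_from_fit",
    "genetic_correlations",
    "residual_correlations",
    "snp_heritability",
    "factorial_coheritability",
    "bivariate_heritability",
    "derived_stats",
    "information_criteria",
    "compare_models",
    "correlation_matrix",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class GeneticComponents:
    """Genetic, residual and implied phenotypic covariance matrices."""

    sigma_g: np.ndarray
    sigma_e: np.ndarray

    @property
    def sigma_p(self) -> np.ndarray:
        return self.sigma_g + self.sigma_e


@dataclass
class DerivedStats:
    """Bundle of derived statistics, each `(estimate, se)` DataFrame pair."""

    rg: pd.DataFrame
    rg_se: pd.DataFrame
    re: pd.DataFrame
    re_se: pd.DataFrame
    snp_h2: pd.Series
    snp_h2_se: pd.Series
    f2: pd.DataFrame
    f2_se: pd.DataFrame
    h2_biv: pd.DataFrame | None
    h2_biv_se: pd.DataFrame | None

    def ci95(self, estimate, se):
        """Normal-approximation 95% interval: estimate +/- 1.96*SE."""
        return estimate - _Z95 * se, estimate + _Z95 * se


def components_from_fit(fit: FitResult) -> GeneticComponents:
    """Genetic and residual covariance implied by the fitted loadings."""
    lm = fit.loadings
    return GeneticComponents(
        sigma_g=lm.lambda_a @ lm.lambda_a.T,
        sigma_e=lm.lambda_e @ lm.lambda_e.T,
    )


def correlation_matrix(sigma: np.ndarray) -> np.ndarray:
    """Covariance -> correlation; pairs with a zero variance become NaN."""
    sd = np.sqrt(np.diag(sigma))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = sigma / np.outer(sd, sd)
    R[~np.isfinite(R)] = np.nan
    return R


# ---------------------------------------------------------------------------
# delta method plumbing
# ---------------------------------------------------------------------------

def _jacobian(func, theta: np.ndarray, rel: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of a vector statistic w.r.t. theta."""
    f0 = np.asarray(func(theta), dtype=float)
    J = np.zeros((f0.size, theta.size))
    for i in range(theta.size):
        h = rel * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        J[:, i] = (np.asarray(func(tp), dtype=float)
                   - np.asarray(func(tm), dtype=float)) / (2.0 * h)
    return J


def _delta_se(fit: FitResult, func) -> np.ndarray:
    """SEs of the vector statistic ``func(theta)`` at the fitted parameters."""
    f0 = np.asarray(func(fit.estimates), dtype=float)
    if fit.param_vcov is None:
        return np.full(f0.size, np.nan)
    J = _jacobian(func, fit.estimates)
    var = np.einsum("ij,jk,ik->i", J, fit.param_vcov, J)
    var[var < 0] = np.nan
    return np.sqrt(var)


def _corr_stat(fit: FitResult, which: str):
    p = fit.spec.p
    iu = np.triu_indices(p, 1)

    def stat(theta: np.ndarray) -> np.ndarray:
        lm = fit.spec.loadings(theta)
        L = lm.lambda_a if which == "genetic" else lm.lambda_e
        S = L @ L.T
        sd = np.sqrt(np.clip(np.diag(S), 1e-300, None))
        return (S / np.outer(sd, sd))[iu]

    return stat, iu


def _corr_with_se(fit: FitResult, which: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    comp = components_from_fit(fit)
    S = comp.sigma_g if which == "genetic" else comp.sigma_e
    R = correlation_matrix(S)
    stat, iu = _corr_stat(fit, which)
    se_flat = _delta_se(fit, stat)
    SE = np.full_like(R, np.nan)
    SE[iu] = se_flat
    SE[(iu[1], iu[0])] = se_flat
    np.fill_diagonal(SE, 0.0)
    # zero-variance traits: report the pair as missing (boundary)
    zero = np.diag(S) <= 1e-12
    R[zero, :] = np.nan
    R[:, zero] = np.nan
    names = list(fit.spec.trait_names)
    return (pd.DataFrame(R, index=names, columns=names),
            pd.DataFrame(SE, index=names, columns=names))


def genetic_correlations(fit: FitResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genetic correlation matrix and delta-method SEs.

    ``r_g = sigma_g12 / sqrt(sigma_g1^2 sigma_g2^2)``; pairs involving a
    zero genetic variance are reported missing.
    """
    return _corr_with_se(fit, "genetic")


def residual_correlations(fit: FitResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residual correlation matrix and delta-method SEs (same form as r_g)."""
    return _corr_with_se(fit, "residual")


def snp_heritability(fit: FitResult) -> tuple[pd.Series, pd.Series]:
    """Per-trait SNP heritability ``sigma_g_tt / (sigma_g_tt + sigma_e_tt)``."""
    def stat(theta: np.ndarray) -> np.ndarray:
        lm = fit.spec.loadings(theta)
        vg = np.sum(lm.lambda_a ** 2, axis=1)
        ve = np.sum(lm.lambda_e ** 2, axis=1)
        return vg / (vg + ve)

    names = list(fit.spec.trait_names)
    return (pd.Series(stat(fit.estimates), index=names, name="snp_h2"),
            pd.Series(_delta_se(fit, stat), index=names, name="se"))


def factorial_coheritability(fit: FitResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Factor x trait table of factorial co-heritabilities with SEs.

    ``f2(i, t)`` is the squared loading of genetic factor ``i`` on trait
    ``t`` over the trait's total genetic variance; rows with zero total
    genetic variance are reported missing.
    """
    p = fit.spec.p
    qa = fit.loadings.lambda_a.shape[1]

    def stat(theta: np.ndarray) -> np.ndarray:
        La = fit.spec.loadings(theta).lambda_a
        tot = np.sum(La ** 2, axis=1)
        tot = np.clip(tot, 1e-300, None)
        return (La ** 2 / tot[:, None]).ravel()

    vals = stat(fit.estimates).reshape(p, qa)
    ses = _delta_se(fit, stat).reshape(p, qa)
    tot = np.sum(fit.loadings.lambda_a ** 2, axis=1)
    vals[tot <= 1e-12, :] = np.nan
    names = list(fit.spec.trait_names)
    cols = fit.spec.genetic_factor_names
    return (pd.DataFrame(vals, index=names, columns=cols),
            pd.DataFrame(ses, index=names, columns=cols))


def bivariate_heritability(
    fit: FitResult,
    observed_cov: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise bivariate heritability ``sigma_g12 / sigma_p12``.

    ``sigma_g12`` comes from the unstandardized fitted loadings and
    ``sigma_p12`` from the observed covariance of the (rank-transformed)
    phenotypes.  The SE is approximated by ``SE(sigma_g12) / sigma_p12``
    (the sampling error of the phenotypic covariance is comparatively
    negligible).  Pairs with ``|sigma_p12| < 1e-8`` are reported missing.
    """
    observed_cov = np.asarray(observed_cov, dtype=float)
    p = fit.spec.p
    if observed_cov.shape != (p, p):
        raise NumericalDegeneracyError("observed_cov shape does not match traits")
    iu = np.triu_indices(p, 1)

    def gcov(theta: np.ndarray) -> np.ndarray:
        La = fit.spec.loadings(theta).lambda_a
        return (La @ La.T)[iu]

    sg = gcov(fit.estimates)
    sg_se = _delta_se(fit, gcov)
    sp = observed_cov[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        h2 = sg / sp
        h2_se = sg_se / np.abs(sp)
    unstable = np.abs(sp) < 1e-8
    h2[unstable] = np.nan
    h2_se[unstable] = np.nan
    names = list(fit.spec.trait_names)
    H = np.full((p, p), np.nan)
    S = np.full((p, p), np.nan)
    H[iu] = h2
    H[(iu[1], iu[0])] = h2
    S[iu] = h2_se
    S[(iu[1], iu[0])] = h2_se
    return (pd.DataFrame(H, index=names, columns=names),
            pd.DataFrame(S, index=names, columns=names))


def derived_stats(fit: FitResult,
                  observed_cov: np.ndarray | None = None) -> DerivedStats:
    """All derived statistics for one fit (bivariate h2 only when the
    observed phenotypic covariance is supplied)."""
    rg, rg_se = genetic_correlations(fit)
    re, re_se = residual_correlations(fit)
    h2, h2_se = snp_heritability(fit)
    f2, f2_se = factorial_coheritability(fit)
    if observed_cov is not None:
        hb, hb_se = bivariate_heritability(fit, observed_cov)
    else:
        hb = hb_se = None
    return DerivedStats(rg=rg, rg_se=rg_se, re=re, re_se=re_se,
                        snp_h2=h2, snp_h2_se=h2_se, f2=f2, f2_se=f2_se,
                        h2_biv=hb, h2_biv_se=hb_se)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """``AIC = -2 LL + 2k``; ``BIC = -2 LL + k ln(n)`` with ``n`` the number
    of individuals in the analysis sample."""
    if n < 1:
        raise NumericalDegeneracyError("n must be >= 1")
    m2ll = -2.0 * loglik
    return m2ll + 2.0 * k, m2ll + k * np.log(n)


def compare_models(fits, saturated, n: int) -> pd.DataFrame:
    """Comparison table versus the saturated model.

    ``fits`` maps model name -> object with ``loglik`` and ``k`` attributes
    (a :class:`~gsemkit.fit.FitResult` qualifies).  Reports LL, -2LL, k,
    AIC, BIC, the LRT against the saturated model (naive chi-square with
    ``df = k_sat - k``), and flags the lowest-BIC model as selected.
    """
    if isinstance(fits, (list, tuple)):
        fits = {getattr(f.spec, "name", f"model{i}"): f
                for i, f in enumerate(fits)}
    m2ll_sat = -2.0 * saturated.loglik
    rows = []
    for name, f in fits.items():
        aic, bic = information_criteria(f.loglik, f.k, n)
        dchi2 = (-2.0 * f.loglik) - m2ll_sat
        ddf = saturated.k - f.k
        if ddf < 0:
            raise DatasetMismatchError(
                f"model {name!r} has more parameters than the saturated model"
            )
        if dchi2 < -1e-4:
            raise DatasetMismatchError(
                f"model {name!r} exceeds the saturated likelihood "
                f"(delta chi2 = {dchi2:.6f}); were the fits on the same data?"
            )
        dchi2 = max(dchi2, 0.0)
        pval = sps.chi2.sf(dchi2, ddf) if ddf > 0 else (np.nan if dchi2 == 0 else 0.0)
        rows.append({
            "model": name, "LL": f.loglik, "minus2LL": -2.0 * f.loglik,
            "k": f.k, "AIC": aic, "BIC": bic,
            "delta_chi2": dchi2, "delta_df": ddf, "p_value": pval,
        })
    out = pd.DataFrame(rows).set_index("model")
    out["selected"] = out["BIC"] == out["BIC"].min()
    return out
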