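"""Maximum-likelihood estimation of factor-structured AE models on a GRM.

The data model: stacked trait values ``vec(Y)`` are multivariate normal with
zero mean (phenotypes are pre-residualized and rank-transformed) and
covariance ``Sigma_g (x) G + Sigma_e (x) I``, where ``G`` is the GRM,
``Sigma_g = La La'`` and ``Sigma_e = Le Le'`` come from the model loadings.

Two likelihood engines are provided:

* ``rotation`` — complete cases only.  Eigendecompose ``G = U D U'`` once,
  rotate each trait vector by ``U'``; rotated individuals are independent
  with per-individual covariance ``d_i Sigma_g + Sigma_e``.  Evaluation is
  O(p^3 + n p) per parameter vector via a generalized eigendecomposition of
  ``(Sigma_g, Sigma_e)``, which makes desk-scale fits fast.
* ``direct`` — accepts missing entries.  Assembles the observed-entry
  covariance ``Sigma_g (x) G + Sigma_e (x) I`` explicitly and evaluates one
  multivariate-normal log-density (full-information likelihood over the
  union sample).  Memory-bound; intended for n up to a couple thousand.

Standard errors come from the inverse of the observed information
(finite-difference negative Hessian of the log-likelihood at the optimum);
per-loading Wald tests divide estimates by those SEs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats as sps

from .exceptions import ConditioningError, ConvergenceError, ValidationError
from .model import LoadingMatrices, ModelSpec, implied_covariance
from .pheno import AnalysisDataset

__all__ = [
    "FitResult",
    "loglik",
    "fit_ml",
    "wald_tests",
    "observed_information",
]

logger = logging.getLogger("gsemkit.fit")

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: ModelSpec
    estimates: np.ndarray
    loglik: float
    n_used: int
    k: int
    param_vcov: np.ndarray | None
    converged: bool
    n_restarts_agreeing: int
    engine: str
    messages: list[str] = field(default_factory=list)

    @property
    def loadings(self) -> LoadingMatrices:
        return self.spec.loadings(self.estimates)

    @property
    def se(self) -> np.ndarray:
        """Per-parameter SEs (NaN where the information was not invertible)."""
        if self.param_vcov is None:
            return np.full(self.k, np.nan)
        d = np.diag(self.param_vcov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    @property
    def wald(self) -> pd.DataFrame:
        return wald_tests(self)

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.loglik


# ---------------------------------------------------------------------------
# likelihood engines
# ---------------------------------------------------------------------------

def _grm_eigen(dataset: AnalysisDataset) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose the dataset GRM, flooring eigenvalues at zero.

    A zero floor (rather than a small positive jitter) keeps the rotation
    engine numerically identical to the direct engine, which consumes the
    GRM as-is; a zero eigenvalue is harmless because the residual
    covariance keeps each rotated observation nonsingular.
    """
    d, U = np.linalg.eigh(dataset.grm.values)
    n_clip = int(np.sum(d < 0.0))
    if n_clip:
        if d.min() < -1e-4:
            raise ConditioningError(
                f"GRM has strongly negative eigenvalue {d.min():.3e}"
            )
        # one near-zero eigenvalue is generic (in-sample standardization
        # centers the SNP matrix), so log rather than warn
        logger.info("clamped %d negative GRM eigenvalue(s) to 0", n_clip)
        d = np.clip(d, 0.0, None)
    return d, U


def _rotation_context(dataset: AnalysisDataset) -> tuple[np.ndarray, np.ndarray]:
    """(eigenvalues, rotated phenotypes) for the rotation engine."""
    if not dataset.mask.all():
        raise ValidationError(
            "rotation engine requires complete cases; call "
            "dataset.complete_cases() or use engine='direct'"
        )
    d, U = _grm_eigen(dataset)
    return d, U.T @ dataset.y


def _loglik_rotation(Sg: np.ndarray, Se: np.ndarray,
                     d: np.ndarray, ystar: np.ndarray) -> float:
    """Sum of rotated per-individual MVN log-densities.

    Simultaneous diagonalization: with ``Phi' Se Phi = I`` and
    ``Phi' Sg Phi = diag(mu)``, the covariance ``d_i Sg + Se`` has log-det
    ``logdet(Se) + sum_t log(1 + d_i mu_t)`` and quadratic form
    ``sum_t z_it^2 / (1 + d_i mu_t)`` for ``z_i = Phi' y*_i``.
    """
    n, p = ystar.shape
    try:
        ce = np.linalg.cholesky(Se)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_se = 2.0 * float(np.sum(np.log(np.diag(ce))))
    try:
        mu, phi = sla.eigh(Sg, Se)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        return -np.inf
    mu = np.clip(mu, 0.0, None)  # Sg is PSD by construction
    Z = ystar @ phi
    denom = 1.0 + np.outer(d, mu)
    if np.any(denom <= 0):
        return -np.inf
    quad = float(np.sum(Z * Z / denom))
    logdets = n * logdet_se + float(np.sum(np.log(denom)))
    return -0.5 * (n * p * _LOG2PI + logdets + quad)


def _loglik_direct(Sg: np.ndarray, Se: np.ndarray, dataset: AnalysisDataset) -> float:
    """Full-information MVN log-density over all observed trait entries."""
    G = dataset.grm.values
    n, p = dataset.y.shape
    if n * p > 6000:
        warnings.warn(
            f"direct engine assembles a {n * p}x{n * p} covariance; "
            "consider the rotation engine on complete cases", stacklevel=3,
        )
    obs = np.where(dataset.mask.ravel())[0]   # individual-major, trait-minor
    C = np.kron(G, Sg)
    C += np.kron(np.eye(n), Se)
    C = C[np.ix_(obs, obs)]
    yv = dataset.y.ravel()[obs]
    try:
        cf = sla.cho_factor(C, lower=True, check_finite=False)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    quad = float(yv @ sla.cho_solve(cf, yv, check_finite=False))
    return -0.5 * (obs.size * _LOG2PI + logdet + quad)


def loglik(
    spec: ModelSpec,
    params: np.ndarray,
    dataset: AnalysisDataset,
    engine: str = "rotation",
) -> float:
    """Model log-likelihood at ``params`` (zero-mean multivariate AE model).

    Returns ``-inf`` (no exception) when the implied covariance is singular
    at the evaluation point.
    """
    lm = spec.loadings(params)
    Sg = lm.lambda_a @ lm.lambda_a.T
    Se = lm.lambda_e @ lm.lambda_e.T
    if engine == "rotation":
        d, ystar = _rotation_context(dataset)
        return _loglik_rotation(Sg, Se, d, ystar)
    if engine == "direct":
        return _loglik_direct(Sg, Se, dataset)
    raise ValidationError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _start_from_sample_cov(spec: ModelSpec, dataset: AnalysisDataset) -> np.ndarray:
    """Start 0: split the complete-case sample covariance evenly into the
    genetic and residual parts and map each half into the structure."""
    complete = dataset.mask.all(axis=1)
    yc = dataset.y[complete]
    if yc.shape[0] < spec.p + 2:
        S = np.eye(spec.p)
    else:
        S = np.cov(yc, rowvar=False)
        S = np.atleast_2d(S)
    half = S / 2.0 + 1e-6 * np.eye(spec.p)
    la = _structure_start(spec.genetic_structure, half)
    le = _structure_start(spec.residual_structure, half)
    return spec.pack(LoadingMatrices(lambda_a=la, lambda_e=le))


def _structure_start(structure: str, target: np.ndarray) -> np.ndarray:
    p = target.shape[0]
    if structure == "cholesky":
        try:
            return np.linalg.cholesky(target)
        except np.linalg.LinAlgError:
            return np.linalg.cholesky(target + 0.05 * np.eye(p))
    w, v = np.linalg.eigh(target)
    lead = v[:, -1] * np.sqrt(max(w[-1], 1e-3))
    if lead[np.argmax(np.abs(lead))] < 0:
        lead = -lead
    L = np.zeros((p, p + 1))
    L[:, 0] = lead
    resid = np.maximum(np.diag(target) - lead ** 2, 0.05 * np.diag(target))
    L[np.arange(p), np.arange(1, p + 1)] = np.sqrt(resid)
    return L


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def fit_ml(
    spec: ModelSpec,
    dataset: AnalysisDataset,
    engine: str = "rotation",
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-10,
    compute_vcov: bool = True,
) -> FitResult:
    """Maximize the model likelihood from multiple jittered starts.

    Start 0 maps half the complete-case sample covariance into the factor
    structure; subsequent starts multiply it by lognormal noise (sd 0.3).
    The best optimum is sign-canonicalized, and the parameter covariance is
    the inverse observed information at that optimum.
    """
    messages: list[str] = []
    if engine == "rotation" and not dataset.mask.all():
        dataset = dataset.complete_cases()
        messages.append("rotation engine: reduced to complete cases")
    n_used = dataset.n
    k = spec.k
    if n_used < 10 * k:
        messages.append(f"n_used={n_used} below recommended 10*k={10 * k}")

    if engine == "rotation":
        d, ystar = _rotation_context(dataset)

        def ll(theta: np.ndarray) -> float:
            lm = spec.loadings(theta)
            return _loglik_rotation(lm.lambda_a @ lm.lambda_a.T,
                                    lm.lambda_e @ lm.lambda_e.T, d, ystar)
    else:
        def ll(theta: np.ndarray) -> float:
            lm = spec.loadings(theta)
            return _loglik_direct(lm.lambda_a @ lm.lambda_a.T,
                                  lm.lambda_e @ lm.lambda_e.T, dataset)

    def objective(theta: np.ndarray) -> float:
        v = ll(theta)
        return 1e12 if not np.isfinite(v) else -v

    rng = np.random.default_rng(seed)
    theta0 = _start_from_sample_cov(spec, dataset)
    results = []
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 * rng.lognormal(0.0, 0.3, size=k)
        res = optimize.minimize(
            objective, start, method="L-BFGS-B",
            options={"maxiter": 3000, "maxfun": 200000,
                     "ftol": tol, "gtol": 1e-9},
        )
        if np.isfinite(res.fun) and res.fun < 1e11:
            results.append(res)
    if not results:
        raise ConvergenceError("no optimization start reached a finite optimum")
    best = min(results, key=lambda r: r.fun)
    agree = sum(1 for r in results if r.fun - best.fun <= 1e-4)
    theta_hat = spec.canonicalize(best.x)
    ll_hat = ll(theta_hat)

    vcov = None
    if compute_vcov:
        info = _observed_information(ll, theta_hat)
        vcov, note = _invert_information(info)
        if note:
            messages.append(note)

    return FitResult(
        spec=spec,
        estimates=theta_hat,
        loglik=float(ll_hat),
        n_used=n_used,
        k=k,
        param_vcov=vcov,
        converged=bool(best.success or agree >= 2),
        n_restarts_agreeing=agree,
        engine=engine,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# observed information and Wald tests
# ---------------------------------------------------------------------------

def _steps(theta: np.ndarray, rel: float = 1e-4, floor: float = 1e-6) -> np.ndarray:
    return np.maximum(rel * np.abs(theta), floor)


def _observed_information(ll, theta: np.ndarray,
                          rel: float = 1e-4, floor: float = 1e-6) -> np.ndarray:
    """Negative Hessian of the log-likelihood by central finite differences.

    Shrinks the stencil once (x0.1) if any evaluation is non-finite.
    """
    for attempt in range(2):
        h = _steps(theta, rel * (0.1 ** attempt), floor * (0.1 ** attempt))
        k = theta.size
        H = np.empty((k, k))
        f0 = ll(theta)
        ok = np.isfinite(f0)
        for i in range(k):
            if not ok:
                break
            ei = np.zeros(k)
            ei[i] = h[i]
            fp, fm = ll(theta + ei), ll(theta - ei)
            if not (np.isfinite(fp) and np.isfinite(fm)):
                ok = False
                break
            H[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                fpp, fpm = ll(theta + ei + ej), ll(theta + ei - ej)
                fmp, fmm = ll(theta - ei + ej), ll(theta - ei - ej)
                if not np.all(np.isfinite([fpp, fpm, fmp, fmm])):
                    ok = False
                    break
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
        if ok:
            H = (H + H.T) / 2.0
            return -H
    raise ConditioningError("non-finite log-likelihood within the Hessian stencil")


def observed_information(
    spec: ModelSpec,
    params: np.ndarray,
    dataset: AnalysisDataset,
    engine: str = "rotation",
) -> np.ndarray:
    """Observed information (negative finite-difference Hessian of the
    log-likelihood) at ``params``; symmetrized."""
    params = np.asarray(params, dtype=float)
    return _observed_information(lambda t: loglik(spec, t, dataset, engine), params)


def _invert_information(info: np.ndarray) -> tuple[np.ndarray | None, str | None]:
    w = np.linalg.eigvalsh((info + info.T) / 2.0)
    if w.min() <= 0:
        return None, (
            "observed information not positive definite "
            f"(min eigenvalue {w.min():.3e}); SEs unavailable — estimates may "
            "sit on a boundary or the model may be unidentified here"
        )
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None, "observed information numerically singular; SEs unavailable"
    return (vcov + vcov.T) / 2.0, None


def wald_tests(fit: FitResult, alpha: float = 0.05,
               experimentwide: float = 0.007) -> pd.DataFrame:
    """Per-parameter Wald table: z = estimate/SE, two-sided normal p.

    Flags significance at the nominal 0.05 level and at the stricter
    experiment-wide 0.007 threshold.  Rows with missing SEs carry NaN
    statistics rather than raising.
    """
    se = fit.se
    est = fit.estimates
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
        pvals = 2.0 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({
        "parameter": fit.spec.param_names,
        "estimate": est,
        "se": se,
        "z": z,
        "p": pvals,
        "sig_nominal": pvals <= alpha,
        "sig_experimentwide": pvals <= experimentwide,
    })


def model_implied_covariance(fit: FitResult, lam: float = 1.0) -> np.ndarray:
    """Convenience: implied trait covariance at relatedness weight ``lam``."""
    return implied_covariance(fit.loadings, lam)
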