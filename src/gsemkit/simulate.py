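"""Synthetic genotype and phenotype generation for factor-structured AE models.

The generator emulates a population-based sample of unrelated individuals
with several standardized traits whose genetic covariance follows a
one-common-factor + trait-specific structure and whose residual covariance
shows strong within-domain but near-zero cross-domain correlations.  Two
routes produce phenotypes with the same model-implied covariance:

* **genotype-level** — simulate biallelic dosages, estimate the GRM from
  them, then draw factor scores from that realized GRM (exercises the GRM
  estimator);
* **GRM-direct** — draw multivariate-normal factor scores from a supplied
  relatedness matrix via its symmetric square root (fast path).

All randomness flows from one scenario seed through a spawned
``SeedSequence`` stream, so every sub-draw (genetic scores, residual
scores, missingness) is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConditioningError, ValidationError
from .grm import GRMatrix, compute_grm
from .model import LoadingMatrices
from .pheno import PhenotypeTable

__all__ = ["Scenario", "simulate_genotypes", "simulate_phenotypes", "preset",
           "simulate_study"]


@dataclass
class Scenario:
    """A stated synthetic world: truth loadings plus sampling dimensions.

    Presets keep every trait's total implied variance at 1 (standardized
    scale), so per-trait truth heritability is the row-sum of squared
    genetic loadings.
    """

    trait_names: list[str]
    lambda_a: np.ndarray
    lambda_e: np.ndarray
    n: int = 1000
    m: int = 5000
    missing_rates: np.ndarray = field(default=None)  # type: ignore[assignment]
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        self.lambda_a = np.asarray(self.lambda_a, dtype=float)
        self.lambda_e = np.asarray(self.lambda_e, dtype=float)
        p = len(self.trait_names)
        if self.lambda_a.shape[0] != p or self.lambda_e.shape[0] != p:
            raise ValidationError("loading matrices do not match trait count")
        if self.missing_rates is None:
            self.missing_rates = np.zeros(p)
        self.missing_rates = np.asarray(self.missing_rates, dtype=float)
        if self.missing_rates.shape != (p,):
            raise ValidationError("missing_rates must have one entry per trait")

    @property
    def p(self) -> int:
        return len(self.trait_names)

    @property
    def loadings(self) -> LoadingMatrices:
        return LoadingMatrices(lambda_a=self.lambda_a, lambda_e=self.lambda_e)

    @property
    def h2(self) -> np.ndarray:
        """Truth per-trait heritability (row-sums of squared genetic loadings)."""
        return np.sum(self.lambda_a ** 2, axis=1)

    @property
    def sigma_g(self) -> np.ndarray:
        return self.lambda_a @ self.lambda_a.T

    @property
    def sigma_e(self) -> np.ndarray:
        return self.lambda_e @ self.lambda_e.T

    def total_variance(self) -> np.ndarray:
        return np.diag(self.sigma_g + self.sigma_e)


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate an ``(n, m)`` dosage matrix of unrelated individuals.

    Per-SNP allele frequency is uniform on ``maf_range``; dosages are
    ``Binomial(2, p)`` independently across individuals (Hardy-Weinberg,
    no LD).
    """
    if n < 1 or m < 1:
        raise ValidationError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValidationError("maf_range must lie within (0, 0.5]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    freqs = rng.uniform(lo, hi, size=m)
    return rng.binomial(2, freqs, size=(n, m)).astype(float)


def _symmetric_sqrt(G: np.ndarray) -> np.ndarray:
    d, U = np.linalg.eigh(G)
    if d.min() < -1e-4:
        raise ConditioningError(
            f"relatedness matrix far from PSD (min eigenvalue {d.min():.3e})"
        )
    d = np.clip(d, 0.0, None)
    return (U * np.sqrt(d)) @ U.T


def simulate_phenotypes(
    grm: GRMatrix,
    scenario: Scenario,
    seed: int | None = None,
) -> PhenotypeTable:
    """Draw phenotypes from the AE factor model on a realized GRM.

    Each genetic factor score vector is multivariate normal with covariance
    ``G`` (via the symmetric square root of ``G``); residual factor scores
    are iid standard normal.  Trait ``t`` is the loading-weighted sum of its
    factor scores.  Missingness is injected per trait, completely at random,
    at ``scenario.missing_rates``.
    """
    n = grm.n
    p = scenario.p
    qa = scenario.lambda_a.shape[1]
    qe = scenario.lambda_e.shape[1]
    root = np.random.SeedSequence(scenario.seed if seed is None else seed)
    ss_gen, ss_res, ss_miss = root.spawn(3)
    rng_gen = np.random.default_rng(ss_gen)
    rng_res = np.random.default_rng(ss_res)
    rng_miss = np.random.default_rng(ss_miss)

    sqrt_g = _symmetric_sqrt(grm.values)
    g_scores = sqrt_g @ rng_gen.standard_normal((n, qa))
    e_scores = rng_res.standard_normal((n, qe))
    y = g_scores @ scenario.lambda_a.T + e_scores @ scenario.lambda_e.T

    for t in range(p):
        rate = scenario.missing_rates[t]
        if rate > 0:
            y[rng_miss.random(n) < rate, t] = np.nan

    fids, iids = zip(*grm.ids)
    df = pd.DataFrame({"FID": fids, "IID": iids})
    for t, name in enumerate(scenario.trait_names):
        df[name] = y[:, t]
    return PhenotypeTable(data=df, trait_names=list(scenario.trait_names),
                          covariate_names=[], state="raw")


def _ip_lambda_a(common_shares, specific_shares) -> np.ndarray:
    """Independent-pathway genetic loadings from phenotypic-variance shares."""
    c = np.sqrt(np.asarray(common_shares, dtype=float))
    s = np.sqrt(np.asarray(specific_shares, dtype=float))
    p = c.size
    La = np.zeros((p, p + 1))
    La[:, 0] = c
    La[np.arange(p), np.arange(1, p + 1)] = s
    return La


def _residual_chol(h2: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Cholesky of the residual covariance with variances ``1 - h2``."""
    v = 1.0 - h2
    sigma_e = np.sqrt(np.outer(v, v)) * corr
    return np.linalg.cholesky(sigma_e)


def _corr_from_pairs(p: int, pairs: dict[tuple[int, int], float]) -> np.ndarray:
    R = np.eye(p)
    for (i, j), r in pairs.items():
        R[i, j] = R[j, i] = r
    return R


def preset(name: str, n: int = 1000, m: int = 5000, seed: int = 0,
           missing: bool = True) -> Scenario:
    """Named scenarios parameterized from the study's reported structure.

    ``multidomain`` — five traits (spelling, phonemic awareness, passage
    reading, listening comprehension, non-word repetition): one common
    genetic factor with phenotypic-variance shares (0.27, 0.31, 0.45, 0.13,
    0.14), specific genetic factors only for listening comprehension (0.17)
    and non-word repetition (0.12); residual Cholesky with strong
    literacy-phonology correlations and near-zero language/PWM cross-domain
    residual correlations.  ``reading_fluency`` — six reading-fluency
    measures with common shares spanning 0.27-0.47 and small specific
    factors.  ``null_pleiotropy`` — five traits with diagonal genetic
    loadings (no shared genetics), for type-I-error-style checks.

    ``missing=False`` zeroes the per-trait missingness rates (complete-data
    runs for the fast rotation engine).
    """
    if name == "multidomain":
        traits = ["spelling", "phon_aware", "passage_reading",
                  "listening_comp", "nonword_rep"]
        common = [0.27, 0.31, 0.45, 0.13, 0.14]
        specific = [0.0, 0.0, 0.0, 0.17, 0.12]
        La = _ip_lambda_a(common, specific)
        h2 = La[:, 0] ** 2 + np.diag(La[:, 1:]) ** 2
        # reported residual correlations where printed; within-literacy
        # values are illustrative moderate ones (full residual structure is
        # not published)
        pairs = {
            (0, 1): 0.45, (0, 2): 0.67, (1, 2): 0.40,
            (0, 3): 0.02, (1, 3): 0.11, (2, 3): 0.08,
            (0, 4): 0.15, (1, 4): 0.15, (2, 4): 0.15, (3, 4): 0.20,
        }
        Le = _residual_chol(h2, _corr_from_pairs(5, pairs))
        rates = np.array([0.13, 0.11, 0.22, 0.17, 0.18])
    elif name == "reading_fluency":
        traits = ["nw_read_acc", "nw_read_speed", "word_read_acc",
                  "word_read_speed", "passage_read_acc", "passage_read_speed"]
        common = [0.38, 0.35, 0.40, 0.27, 0.47, 0.42]
        specific = [0.0, 0.02, 0.03, 0.06, 0.03, 0.0]
        La = _ip_lambda_a(common, specific)
        h2 = La[:, 0] ** 2 + np.diag(La[:, 1:]) ** 2
        R = np.full((6, 6), 0.5)
        np.fill_diagonal(R, 1.0)
        Le = _residual_chol(h2, R)
        rates = np.array([0.05, 0.30, 0.05, 0.30, 0.14, 0.14])
    elif name == "null_pleiotropy":
        traits = [f"trait{i + 1}" for i in range(5)]
        La = np.diag(np.sqrt(np.full(5, 0.35)))
        Le = np.diag(np.sqrt(np.full(5, 0.65)))
        rates = np.zeros(5)
    else:
        raise ValidationError(f"unknown preset {name!r}")
    if not missing:
        rates = np.zeros(len(traits))
    return Scenario(trait_names=traits, lambda_a=La, lambda_e=Le,
                    n=n, m=m, missing_rates=rates, seed=seed, name=name)


def simulate_study(
    scenario: Scenario,
    route: str = "genotype",
    grm: GRMatrix | None = None,
    maf_range: tuple[float, float] = (0.01, 0.5),
    maf_min: float = 0.01,
) -> tuple[GRMatrix, PhenotypeTable]:
    """One full draw: relatedness matrix plus phenotypes.

    ``route='genotype'`` simulates dosages and estimates the GRM from them
    (exercises the GRM estimator); ``route='grm_direct'`` draws factor
    scores from a caller-supplied ``grm`` (fast path, e.g. to reuse one
    realized GRM across phenotype replicates).  Both routes share the
    phenotype model, so they imply the same trait covariance.
    """
    if route not in ("genotype", "grm_direct"):
        raise ValidationError(f"unknown route {route!r}")
    root = np.random.SeedSequence(scenario.seed)
    ss_geno, ss_pheno = root.spawn(2)
    if route == "grm_direct":
        if grm is None:
            raise ValidationError("route='grm_direct' requires a grm argument")
    else:
        rng = np.random.default_rng(ss_geno)
        X = simulate_genotypes(scenario.n, scenario.m, maf_range, rng)
        grm = compute_grm(X, maf_min=maf_min)
    pheno = simulate_phenotypes(grm, scenario, seed=int(ss_pheno.entropy % (2**31)))
    return grm, pheno
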