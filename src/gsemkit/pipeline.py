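"""Two-stage study orchestration: prune -> transform -> align -> fit -> compare.

A stage takes a GRM prefix and a phenotype file, prepares the data
(relatedness pruning, per-trait covariate residualization, rank transform,
GRM alignment), fits the requested factor structures, compares them by
AIC/BIC/LRT against the saturated Cholesky model, and derives the genetic
statistics for the lowest-BIC model.  Stage 1 models a single domain to
select proxy measures (highest common-factor and highest specific-factor
variance shares); stage 2 re-runs the same machinery across domains with
the chosen proxies.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import GsemError, NotApplicableError, ValidationError
from .fit import FitResult, fit_ml
from .grm import read_grm, prune_related
from .model import from_preset, standardize_loadings
from .pheno import align, read_phenotypes, residualize, transform
from .stats import compare_models, derived_stats

__all__ = ["StageConfig", "run_stage", "select_proxies"]

logger = logging.getLogger("gsemkit.pipeline")

_MODEL_PRESETS = ("cholesky", "ip", "ipc")


@dataclass
class StageConfig:
    """Declarative description of one modeling stage."""

    grm_prefix: str
    phenotype_file: str
    traits: list[str]
    out_dir: str
    covariates: list[str] = field(default_factory=list)
    covariate_map: dict[str, list[str]] = field(default_factory=dict)
    relatedness_cutoff: float = 0.05
    models: tuple[str, ...] = _MODEL_PRESETS
    engine: str = "rotation"
    align_mode: str = "complete"
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models:
            raise ValidationError("models list must be non-empty")
        for m in self.models:
            if m not in _MODEL_PRESETS:
                raise ValidationError(f"unknown model preset {m!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "StageConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def _correlogram_long(rg: pd.DataFrame, re: pd.DataFrame,
                      rg_se: pd.DataFrame, re_se: pd.DataFrame) -> pd.DataFrame:
    """Long-format table: lower triangle genetic, upper triangle residual."""
    rows = []
    names = list(rg.index)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            kind = "genetic" if i > j else "residual"
            src, src_se = (rg, rg_se) if i > j else (re, re_se)
            rows.append({"trait_row": a, "trait_col": b, "kind": kind,
                         "estimate": src.iloc[i, j], "se": src_se.iloc[i, j]})
    return pd.DataFrame(rows)


def run_stage(config: StageConfig) -> dict:
    """Execute one stage end to end; returns the report dict.

    Writes ``comparison.csv``, ``derived.csv``, ``report.json`` and
    ``run.log`` under ``config.out_dir``.  Any stage failure aborts with
    the stage name and removes partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = [out / n for n in
                 ("comparison.csv", "derived.csv", "report.json", "run.log")]
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    t0 = time.time()
    try:
        stage = "read_grm"
        grm = read_grm(config.grm_prefix)
        logger.info("read GRM: n=%d", grm.n)

        stage = "prune_related"
        grm = prune_related(grm, config.relatedness_cutoff)
        logger.info("after relatedness pruning (cutoff %.3g): n=%d",
                    config.relatedness_cutoff, grm.n)

        stage = "phenotypes"
        table = read_phenotypes(config.phenotype_file, config.traits,
                                config.covariates)
        table = residualize(table, config.covariate_map or None)
        table = transform(table)
        logger.info("phenotypes prepared: %d rows, traits=%s",
                    table.n, config.traits)

        stage = "align"
        ds = align(table, grm, config.traits, mode=config.align_mode)
        logger.info("aligned: n=%d (union %d, complete %d)",
                    ds.n, ds.n_union, ds.n_complete)

        stage = "fit"
        fits: dict[str, FitResult] = {}
        for name in config.models:
            t_fit = time.time()
            spec = from_preset(name, config.traits)
            fits[name] = fit_ml(spec, ds, engine=config.engine,
                                n_starts=config.n_starts, seed=config.seed)
            logger.info("fit %s: LL=%.4f k=%d (%.1fs)", name,
                        fits[name].loglik, fits[name].k, time.time() - t_fit)

        stage = "compare"
        if "cholesky" in fits and len(fits) > 1:
            comparison = compare_models(fits, fits["cholesky"], ds.n)
        else:
            only = next(iter(fits.values()))
            from .stats import information_criteria
            aic, bic = information_criteria(only.loglik, only.k, ds.n)
            comparison = pd.DataFrame(
                [{"model": next(iter(fits)), "LL": only.loglik,
                  "minus2LL": -2 * only.loglik, "k": only.k,
                  "AIC": aic, "BIC": bic, "selected": True}]).set_index("model")
        selected_name = comparison.index[comparison["selected"]][0]
        selected = fits[selected_name]
        logger.info("selected model by BIC: %s", selected_name)

        stage = "derive"
        complete = ds.complete_cases()
        obs_cov = np.cov(complete.y, rowvar=False)
        ds_stats = derived_stats(selected, observed_cov=obs_cov)
        long = _correlogram_long(ds_stats.rg, ds_stats.re,
                                 ds_stats.rg_se, ds_stats.re_se)

        stage = "write"
        comparison.to_csv(out / "comparison.csv")
        long.to_csv(out / "derived.csv", index=False)
        report = {
            "config": {
                "traits": list(config.traits),
                "models": list(config.models),
                "engine": config.engine,
                "align_mode": config.align_mode,
                "relatedness_cutoff": config.relatedness_cutoff,
                "seed": config.seed,
            },
            "n": ds.n,
            "n_union": ds.n_union,
            "n_complete": ds.n_complete,
            "selected_model": selected_name,
            "comparison": json.loads(
                comparison.reset_index().to_json(orient="records")),
            "fits": {
                name: {
                    "loglik": f.loglik, "k": f.k, "n_used": f.n_used,
                    "converged": f.converged,
                    "n_restarts_agreeing": f.n_restarts_agreeing,
                    "estimates": f.estimates.tolist(),
                    "se": np.where(np.isnan(f.se), None, f.se).tolist(),
                    "param_names": f.spec.param_names,
                } for name, f in fits.items()
            },
            "derived": {
                "snp_h2": ds_stats.snp_h2.round(10).to_dict(),
                "snp_h2_se": ds_stats.snp_h2_se.round(10).to_dict(),
                "rg": ds_stats.rg.round(10).to_dict(),
                "re": ds_stats.re.round(10).to_dict(),
                "f2": ds_stats.f2.round(10).to_dict(),
            },
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        logger.info("stage complete in %.1fs", time.time() - t0)
        return report
    except Exception as exc:
        for path in artifacts:
            if path.name != "run.log" and path.exists():
                path.unlink()
        raise GsemError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def select_proxies(fit: FitResult) -> dict[str, str | None]:
    """Proxy-measure selection from an independent-pathway genetic fit.

    Returns the trait with the largest standardized common-factor variance
    share and the trait with the largest specific-factor share (``None``
    when every specific loading is zero).  Ties break toward the first
    trait in order, with a logged warning.
    """
    if fit.spec.genetic_structure != "independent_pathway":
        raise NotApplicableError(
            "proxy selection requires an independent-pathway genetic structure"
        )
    shares = standardize_loadings(fit.loadings, fit.spec)
    common = shares["AC"].to_numpy()
    p = fit.spec.p
    La = fit.loadings.lambda_a
    specific = (La[np.arange(p), np.arange(1, p + 1)] ** 2
                / np.maximum(np.sum(La ** 2, axis=1)
                             + np.sum(fit.loadings.lambda_e ** 2, axis=1), 1e-300))

    def argmax_with_tie(v: np.ndarray, label: str) -> int:
        top = np.where(v == v.max())[0]
        if top.size > 1:
            logger.warning("tie on %s share; keeping first trait in order", label)
        return int(top[0])

    i_common = argmax_with_tie(common, "common-factor")
    max_specific = None
    if np.any(specific > 0):
        max_specific = fit.spec.trait_names[argmax_with_tie(specific, "specific-factor")]
    return {
        "max_common_trait": fit.spec.trait_names[i_common],
        "max_specific_trait": max_specific,
    }
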