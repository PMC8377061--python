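"""Phenotype preparation: covariate residualization, rank-based inverse-normal
transformation, and alignment of phenotypes to a GRM.

The modeling likelihood assumes zero-mean multivariate-normal traits, so raw
test scores are first residualized on nuisance covariates (age, sex, genetic
principal components, ...) per trait, then rank-transformed to normal
quantiles (Blom offset).  :func:`align` intersects the prepared table with a
GRM and produces the matrix inputs the fitting engines consume.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    CollinearityError,
    DegenerateRankError,
    NoOverlapError,
    ValidationError,
)
from .grm import GRMatrix

__all__ = [
    "PhenotypeTable",
    "AnalysisDataset",
    "read_phenotypes",
    "residualize",
    "rank_inverse_normal",
    "transform",
    "align",
]

_MISSING_CODES = ("", "NA", "NaN", "nan")


@dataclass
class PhenotypeTable:
    """Individuals x (traits + covariates) with missingness.

    ``data`` carries ``FID``/``IID`` plus the named trait and covariate
    columns; ``state`` tracks the preparation stage (``raw`` ->
    ``residualized`` -> ``transformed``).
    """

    data: pd.DataFrame
    trait_names: list[str]
    covariate_names: list[str] = field(default_factory=list)
    state: str = "raw"

    def __post_init__(self) -> None:
        for col in ("FID", "IID"):
            if col not in self.data.columns:
                raise ValidationError(f"phenotype table lacks column {col!r}")
        keys = self.keys
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate FID_IID keys in phenotype table")
        missing = [c for c in self.trait_names + self.covariate_names
                   if c not in self.data.columns]
        if missing:
            raise ValidationError(f"columns not in table: {missing}")

    @property
    def keys(self) -> list[str]:
        return [f"{f}_{i}" for f, i in
                zip(self.data["FID"].astype(str), self.data["IID"].astype(str))]

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass
class AnalysisDataset:
    """Aligned phenotype matrix + GRM ready for likelihood evaluation.

    ``y`` is ``(n, p)`` with ``NaN`` marking missing entries; its row order
    matches ``grm.ids`` exactly.
    """

    y: np.ndarray
    grm: GRMatrix
    trait_names: list[str]
    n_union: int
    n_complete: int

    def __post_init__(self) -> None:
        if self.y.shape[0] != self.grm.n:
            raise ValidationError("y rows and GRM dimension differ")
        if np.any(np.all(np.isnan(self.y), axis=1)):
            raise ValidationError("dataset contains an individual with no observed trait")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.y.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean (n, p): True where observed."""
        return ~np.isnan(self.y)

    def complete_cases(self) -> "AnalysisDataset":
        """Restrict to individuals with every trait observed."""
        keep = np.where(self.mask.all(axis=1))[0]
        if keep.size == 0:
            raise NoOverlapError("no complete cases")
        return AnalysisDataset(
            y=self.y[keep],
            grm=self.grm.subset(keep),
            trait_names=self.trait_names,
            n_union=keep.size,
            n_complete=keep.size,
        )


def read_phenotypes(
    path: str,
    trait_names: list[str],
    covariate_names: list[str] | None = None,
    missing_codes: tuple[str, ...] = _MISSING_CODES,
) -> PhenotypeTable:
    """Read a tab-separated phenotype file (header, first two columns FID IID)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str},
                     na_values=list(missing_codes), keep_default_na=False)
    df = df.rename(columns={df.columns[0]: "FID", df.columns[1]: "IID"})
    return PhenotypeTable(
        data=df,
        trait_names=trait_names,
        covariate_names=covariate_names or [],
        state="raw",
    )


def _design_matrix(df: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    names = ["const"]
    for c in covariates:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy(dtype=float))
                names.append(d)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(f"rank-deficient covariate design: {names}")
    return X


def residualize(
    table: PhenotypeTable,
    per_trait_covariates: dict[str, list[str]] | None = None,
) -> PhenotypeTable:
    """OLS-residualize each trait on its covariate list (plus intercept).

    ``per_trait_covariates`` maps trait name to covariate column names; a
    trait absent from the mapping uses every covariate column of the table,
    and an explicitly empty list passes the trait through unchanged (for
    scores that arrive pre-standardized).  Each regression uses only that
    trait's non-missing rows.
    """
    out = table.data.copy()
    for trait in table.trait_names:
        covs = (per_trait_covariates or {}).get(trait, table.covariate_names)
        if not covs:
            continue
        obs = out[trait].notna()
        for c in covs:
            if out.loc[obs, c].isna().any():
                raise ValidationError(
                    f"covariate {c!r} missing for observed rows of trait {trait!r}"
                )
        X = _design_matrix(out.loc[obs], covs)
        yv = out.loc[obs, trait].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        out.loc[obs, trait] = yv - X @ beta
    return PhenotypeTable(
        data=out,
        trait_names=list(table.trait_names),
        covariate_names=list(table.covariate_names),
        state="residualized",
    )


def rank_inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset.

    Non-missing entries are replaced by standard-normal quantiles of
    ``(rank - offset) / (n_obs + 1 - 2*offset)`` with average ranks for
    ties; missing entries stay missing.
    """
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    n_obs = int(obs.sum())
    if n_obs < 3:
        raise ValidationError("rank transform needs >= 3 non-missing values")
    x = v[obs]
    if np.all(x == x[0]):
        raise DegenerateRankError("all non-missing values identical")
    ranks = sps.rankdata(x, method="average")
    quantiles = sps.norm.ppf((ranks - offset) / (n_obs + 1 - 2 * offset))
    out = np.full_like(v, np.nan)
    out[obs] = quantiles
    return out


def transform(table: PhenotypeTable, offset: float = 3.0 / 8.0) -> PhenotypeTable:
    """Apply :func:`rank_inverse_normal` to every trait column."""
    out = table.data.copy()
    for trait in table.trait_names:
        out[trait] = rank_inverse_normal(out[trait].to_numpy(dtype=float), offset)
    return PhenotypeTable(
        data=out,
        trait_names=list(table.trait_names),
        covariate_names=list(table.covariate_names),
        state="transformed",
    )


def align(
    table: PhenotypeTable,
    grm: GRMatrix,
    traits: list[str] | None = None,
    mode: str = "union",
    require_transformed: bool = True,
) -> AnalysisDataset:
    """Intersect a phenotype table with a GRM and build the analysis matrices.

    ``mode='union'`` keeps individuals with at least one of the listed
    traits observed (the per-model N the likelihood can use with the direct
    engine); ``mode='complete'`` keeps only fully observed rows.  The GRM is
    re-ordered to match the retained phenotype rows.
    """
    if mode not in ("union", "complete"):
        raise ValidationError(f"unknown mode {mode!r}")
    if require_transformed and table.state != "transformed":
        raise ValidationError(
            f"align expects a transformed table, got state={table.state!r} "
            "(pass require_transformed=False to override)"
        )
    traits = list(traits or table.trait_names)
    key_to_row = {k: i for i, k in enumerate(table.keys)}
    grm_pos, tab_pos = [], []
    for gpos, key in enumerate(grm.keys):
        row = key_to_row.get(key)
        if row is not None:
            grm_pos.append(gpos)
            tab_pos.append(row)
    if not grm_pos:
        raise NoOverlapError("no individuals shared between phenotypes and GRM")
    y = table.data.iloc[tab_pos][traits].to_numpy(dtype=float)
    observed_any = ~np.all(np.isnan(y), axis=1)
    observed_all = ~np.any(np.isnan(y), axis=1)
    n_union = int(observed_any.sum())
    n_complete = int(observed_all.sum())
    keep = observed_all if mode == "complete" else observed_any
    if not np.any(keep):
        raise NoOverlapError("no individuals retained after missingness filter")
    sub = grm.subset(np.asarray(grm_pos)[keep])
    return AnalysisDataset(
        y=y[keep],
        grm=sub,
        trait_names=traits,
        n_union=n_union,
        n_complete=n_complete,
    )
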