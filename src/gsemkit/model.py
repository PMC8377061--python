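"""Factor-structure specification for multivariate AE models.

Phenotypic covariance is decomposed into an additive-genetic part scaled by
realized relatedness and a residual part, each structured as either

* a **Cholesky decomposition**: trait ``j`` loads on factors ``1..j``
  (lower-triangular loading matrix, ``p(p+1)/2`` free parameters) — the
  saturated structure spanning any PSD covariance; or
* an **independent pathway** (IP): one common factor loading on all traits
  plus one specific factor per trait (``2p`` free parameters; identified
  for ``p >= 3``).

Three named presets cover the usual model set: ``CHOLESKY`` (both parts
saturated), ``IP`` (both parts independent-pathway) and the hybrid ``IPC``
(independent-pathway genetic part, Cholesky residual part).  All latent
factors have unit variance; scale lives entirely in the loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import IdentificationError, NumericalDegeneracyError, ValidationError

__all__ = [
    "CHOLESKY",
    "IP",
    "IPC",
    "ModelSpec",
    "LoadingMatrices",
    "build_model",
    "from_preset",
    "count_parameters",
    "implied_covariance",
    "standardize_loadings",
]

CHOLESKY = ("cholesky", "cholesky")
IP = ("independent_pathway", "independent_pathway")
IPC = ("independent_pathway", "cholesky")

_PRESETS = {"cholesky": CHOLESKY, "ip": IP, "ipc": IPC}
_STRUCTURES = ("cholesky", "independent_pathway")


def _block_size(structure: str, p: int) -> int:
    return p * (p + 1) // 2 if structure == "cholesky" else 2 * p


def _block_to_matrix(structure: str, p: int, theta: np.ndarray) -> np.ndarray:
    """Free parameters -> loading matrix (column-major fill)."""
    if structure == "cholesky":
        L = np.zeros((p, p))
        k = 0
        for j in range(p):
            for i in range(j, p):
                L[i, j] = theta[k]
                k += 1
        return L
    L = np.zeros((p, p + 1))
    L[:, 0] = theta[:p]          # common factor
    L[np.arange(p), np.arange(1, p + 1)] = theta[p:]  # specific factors
    return L


def _matrix_to_block(structure: str, L: np.ndarray) -> np.ndarray:
    p = L.shape[0]
    if structure == "cholesky":
        return np.concatenate([L[j:, j] for j in range(p)])
    return np.concatenate([L[:, 0], L[np.arange(p), np.arange(1, p + 1)]])


def _block_param_names(structure: str, prefix: str, traits: list[str]) -> list[str]:
    p = len(traits)
    if structure == "cholesky":
        return [f"{prefix}[{traits[i]},{j + 1}]"
                for j in range(p) for i in range(j, p)]
    return ([f"{prefix}c[{t}]" for t in traits]
            + [f"{prefix}s[{t}]" for t in traits])


def _block_factor_names(structure: str, prefix: str, p: int) -> list[str]:
    if structure == "cholesky":
        return [f"{prefix.upper()}{j + 1}" for j in range(p)]
    return [f"{prefix.upper()}C"] + [f"{prefix.upper()}S{j + 1}" for j in range(p)]


@dataclass(frozen=True)
class LoadingMatrices:
    """Genetic and residual loading matrices (traits x factors)."""

    lambda_a: np.ndarray
    lambda_e: np.ndarray


@dataclass(frozen=True)
class ModelSpec:
    """Declarative genetic + residual factor structure for ``p`` traits.

    Owns the deterministic free-parameter ordering: genetic block first,
    then residual block, column-major within each block.
    """

    trait_names: tuple[str, ...]
    genetic_structure: str
    residual_structure: str
    name: str = field(default="custom")

    def __post_init__(self) -> None:
        for s in (self.genetic_structure, self.residual_structure):
            if s not in _STRUCTURES:
                raise ValidationError(f"unknown structure {s!r}")
        if "independent_pathway" in (self.genetic_structure,
                                     self.residual_structure) and self.p < 3:
            raise IdentificationError(
                "independent-pathway structures need p >= 3 traits "
                f"(got p={self.p})"
            )

    @property
    def p(self) -> int:
        return len(self.trait_names)

    @property
    def k(self) -> int:
        return count_parameters(self)

    @property
    def param_names(self) -> list[str]:
        traits = list(self.trait_names)
        return (_block_param_names(self.genetic_structure, "a", traits)
                + _block_param_names(self.residual_structure, "e", traits))

    @property
    def genetic_factor_names(self) -> list[str]:
        return _block_factor_names(self.genetic_structure, "a", self.p)

    @property
    def residual_factor_names(self) -> list[str]:
        return _block_factor_names(self.residual_structure, "e", self.p)

    def loadings(self, theta: np.ndarray) -> LoadingMatrices:
        """Unpack a free-parameter vector into loading matrices."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.k:
            raise ValidationError(f"expected {self.k} parameters, got {theta.size}")
        na = _block_size(self.genetic_structure, self.p)
        return LoadingMatrices(
            lambda_a=_block_to_matrix(self.genetic_structure, self.p, theta[:na]),
            lambda_e=_block_to_matrix(self.residual_structure, self.p, theta[na:]),
        )

    def pack(self, loadings: LoadingMatrices) -> np.ndarray:
        """Inverse of :meth:`loadings`."""
        return np.concatenate([
            _matrix_to_block(self.genetic_structure, loadings.lambda_a),
            _matrix_to_block(self.residual_structure, loadings.lambda_e),
        ])

    def canonicalize(self, theta: np.ndarray) -> np.ndarray:
        """Flip loading-column signs to the canonical identification form.

        Sign flips of whole factor columns never change the implied
        covariance; the conventions are: non-negative Cholesky diagonals,
        non-negative first-nonzero common-factor loading, non-negative
        specific loadings.
        """
        lm = self.loadings(theta)
        la = _canonical_matrix(self.genetic_structure, lm.lambda_a.copy())
        le = _canonical_matrix(self.residual_structure, lm.lambda_e.copy())
        return self.pack(LoadingMatrices(lambda_a=la, lambda_e=le))

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "trait_names": list(self.trait_names),
            "genetic_structure": self.genetic_structure,
            "residual_structure": self.residual_structure,
            "name": self.name,
        }, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        d = yaml.safe_load(text)
        return cls(
            trait_names=tuple(d["trait_names"]),
            genetic_structure=d["genetic_structure"],
            residual_structure=d["residual_structure"],
            name=d.get("name", "custom"),
        )


def _canonical_matrix(structure: str, L: np.ndarray) -> np.ndarray:
    p = L.shape[0]
    if structure == "cholesky":
        for j in range(p):
            if L[j, j] < 0:
                L[:, j] = -L[:, j]
        return L
    nz = np.nonzero(L[:, 0])[0]
    if nz.size and L[nz[0], 0] < 0:
        L[:, 0] = -L[:, 0]
    for j in range(p):
        if L[j, j + 1] < 0:
            L[j, j + 1] = -L[j, j + 1]
    return L


def build_model(
    trait_names: list[str] | tuple[str, ...],
    genetic_structure: str,
    residual_structure: str,
    name: str = "custom",
) -> ModelSpec:
    """Construct a :class:`ModelSpec` (validates identification rules)."""
    return ModelSpec(
        trait_names=tuple(trait_names),
        genetic_structure=genetic_structure,
        residual_structure=residual_structure,
        name=name,
    )


def from_preset(preset: str, trait_names: list[str] | tuple[str, ...]) -> ModelSpec:
    """Build one of the named presets: ``cholesky``, ``ip`` or ``ipc``."""
    key = preset.lower()
    if key not in _PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {list(_PRESETS)}")
    g, r = _PRESETS[key]
    return build_model(trait_names, g, r, name=key)


def count_parameters(spec: ModelSpec) -> int:
    """Free-parameter count: ``p(p+1)/2`` per Cholesky block, ``2p`` per IP block."""
    return (_block_size(spec.genetic_structure, spec.p)
            + _block_size(spec.residual_structure, spec.p))


def implied_covariance(loadings: LoadingMatrices, lam: float = 1.0) -> np.ndarray:
    """Model-implied trait covariance at relatedness weight ``lam``:
    ``lam * La La' + Le Le'`` (always symmetric PSD)."""
    if lam < 0:
        raise ValidationError("relatedness weight must be >= 0")
    S = lam * (loadings.lambda_a @ loadings.lambda_a.T) \
        + loadings.lambda_e @ loadings.lambda_e.T
    return (S + S.T) / 2.0


def standardize_loadings(
    loadings: LoadingMatrices,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Phenotypic-variance share of every factor for every trait.

    Share(factor f, trait t) = squared loading / total implied variance of
    trait t at ``lam = 1``; genetic and residual shares sum to 1 per trait.
    """
    total = (np.sum(loadings.lambda_a ** 2, axis=1)
             + np.sum(loadings.lambda_e ** 2, axis=1))
    if np.any(total <= 0):
        raise NumericalDegeneracyError("zero total implied variance for some trait")
    shares = np.hstack([loadings.lambda_a ** 2, loadings.lambda_e ** 2]) / total[:, None]
    if spec is not None:
        cols = spec.genetic_factor_names + spec.residual_factor_names
        idx = list(spec.trait_names)
    else:
        cols = ([f"A{j + 1}" for j in range(loadings.lambda_a.shape[1])]
                + [f"E{j + 1}" for j in range(loadings.lambda_e.shape[1])])
        idx = [f"trait{i + 1}" for i in range(loadings.lambda_a.shape[0])]
    return pd.DataFrame(shares, index=idx, columns=cols)
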