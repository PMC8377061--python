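"""Genetic relationship matrices (GRMs): construction, I/O and relatedness pruning.

A GRM holds the realized genome-wide relatedness between every pair of
individuals, estimated from allele-frequency-standardized SNP dosages.  The
on-disk dialect is the GCTA binary triplet: ``prefix.grm.bin`` (float32 lower
triangle, diagonal included, row-major individual order), ``prefix.grm.id``
(whitespace-delimited FID IID, no header) and the optional
``prefix.grm.N.bin`` (float32 per-pair SNP counts, same layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyPanelError,
    MalformedFileError,
    MissingCompanionError,
    NumericalDegeneracyError,
    ValidationError,
)

__all__ = ["GRMatrix", "read_grm", "write_grm", "compute_grm", "prune_related"]


@dataclass
class GRMatrix:
    """Symmetric relatedness matrix with individual IDs.

    Parameters
    ----------
    ids
        Ordered ``(family_id, individual_id)`` string pairs, one per row.
    values
        Symmetric ``(n, n)`` relatedness matrix; the diagonal must be
        strictly positive.
    pair_counts
        Optional ``(n, n)`` matrix of SNP counts contributing to each pair.
    """

    ids: list[tuple[str, str]]
    values: np.ndarray
    pair_counts: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [(str(f), str(i)) for f, i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"GRM shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-6, rtol=0):
            raise ValidationError("GRM values are not symmetric")
        # store exact symmetry: mirror the lower triangle
        self.values = np.tril(self.values) + np.tril(self.values, -1).T
        if np.any(np.diag(self.values) <= 0):
            raise ValidationError("GRM diagonal entries must be strictly positive")
        if len(set(self.keys)) != n:
            raise ValidationError("composite FID_IID keys are not unique")
        if self.pair_counts is not None:
            self.pair_counts = np.asarray(self.pair_counts, dtype=float)
            if self.pair_counts.shape != (n, n):
                raise ValidationError("pair_counts shape does not match ids")
            self.pair_counts = (
                np.tril(self.pair_counts) + np.tril(self.pair_counts, -1).T
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def keys(self) -> list[str]:
        """Composite ``FID_IID`` keys in row order."""
        return [f"{f}_{i}" for f, i in self.ids]

    def subset(self, index: np.ndarray) -> "GRMatrix":
        """Return the GRM restricted to ``index`` (positions), order preserved."""
        index = np.asarray(index)
        return GRMatrix(
            ids=[self.ids[i] for i in index],
            values=self.values[np.ix_(index, index)],
            pair_counts=None
            if self.pair_counts is None
            else self.pair_counts[np.ix_(index, index)],
        )


def _tril_pack(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    idx = np.tril_indices(n)
    return values[idx]


def _tril_unpack(stream: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    out[np.tril_indices(n)] = stream
    return out + np.tril(out, -1).T


def read_grm(prefix: str) -> GRMatrix:
    """Read a GCTA binary GRM triplet rooted at ``prefix``.

    ``prefix.grm.bin`` and ``prefix.grm.id`` are required; the pair-count
    file ``prefix.grm.N.bin`` is optional.
    """
    id_path = f"{prefix}.grm.id"
    bin_path = f"{prefix}.grm.bin"
    try:
        id_df = pd.read_csv(id_path, sep=r"\s+", header=None, dtype=str)
    except FileNotFoundError as exc:
        raise MissingCompanionError(f"missing id file: {id_path}") from exc
    ids = list(zip(id_df.iloc[:, 0], id_df.iloc[:, 1]))
    n = len(ids)
    n_entries = n * (n + 1) // 2
    expected = 4 * n_entries
    try:
        stream = np.fromfile(bin_path, dtype="<f4")
    except FileNotFoundError as exc:
        raise MissingCompanionError(f"missing GRM binary: {bin_path}") from exc
    if stream.size != n_entries:
        raise MalformedFileError(
            f"{bin_path}: expected {expected} bytes "
            f"(n={n} lower-triangle float32), found {4 * stream.size}"
        )
    values = _tril_unpack(stream.astype(float), n)
    pair_counts = None
    try:
        nstream = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
        if nstream.size == n_entries:
            pair_counts = _tril_unpack(nstream.astype(float), n)
        elif nstream.size == 1:
            pair_counts = np.full((n, n), float(nstream[0]))
        else:
            raise MalformedFileError(
                f"{prefix}.grm.N.bin: expected {n_entries} or 1 float32 entries, "
                f"found {nstream.size}"
            )
    except FileNotFoundError:
        pass
    return GRMatrix(ids=ids, values=values, pair_counts=pair_counts)


def write_grm(grm: GRMatrix, prefix: str) -> None:
    """Write ``grm`` as a GCTA binary triplet rooted at ``prefix``.

    The pair-count companion ``prefix.grm.N.bin`` is written only when
    ``grm.pair_counts`` is present.
    """
    _tril_pack(grm.values).astype("<f4").tofile(f"{prefix}.grm.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for fid, iid in grm.ids:
            fh.write(f"{fid}\t{iid}\n")
    if grm.pair_counts is not None:
        _tril_pack(grm.pair_counts).astype("<f4").tofile(f"{prefix}.grm.N.bin")


def compute_grm(
    genotypes: np.ndarray,
    maf_min: float = 0.01,
    ids: list[tuple[str, str]] | None = None,
    hard_calls_only: bool = False,
) -> GRMatrix:
    """Estimate a GRM from an ``(n, m)`` dosage matrix.

    Allele frequencies are estimated in-sample.  Entry ``(j, k)`` is the
    average over retained SNPs of
    ``(x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``,
    i.e. the standard allele-frequency-standardized cross-product.  SNPs with
    in-sample minor allele frequency below ``maf_min`` are dropped.

    Parameters
    ----------
    genotypes
        Dosage matrix in [0, 2]; real-valued (imputed) dosages are accepted
        unless ``hard_calls_only`` is set.
    maf_min
        Minimum minor allele frequency for a SNP to be retained.
    ids
        Optional explicit IDs; defaults to ``("F<i>", "I<i>")``.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValidationError("genotypes must be (n>=2, m>=1)")
    if hard_calls_only and not np.all(np.isin(X, (0.0, 1.0, 2.0))):
        raise ValidationError("non-integer dosages present with hard_calls_only=True")
    p = X.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if not np.any(keep):
        raise EmptyPanelError(f"no SNPs remain at maf_min={maf_min}")
    Xk = X[:, keep]
    pk = p[keep]
    zero_var = np.where(Xk.std(axis=0) == 0)[0]
    if zero_var.size:
        orig = np.where(keep)[0][zero_var]
        raise NumericalDegeneracyError(
            f"retained SNP column(s) with zero variance: {orig.tolist()}"
        )
    W = (Xk - 2 * pk) / np.sqrt(2 * pk * (1 - pk))
    m_eff = Xk.shape[1]
    values = (W @ W.T) / m_eff
    values = (values + values.T) / 2.0
    n = X.shape[0]
    if ids is None:
        ids = [(f"F{i}", f"I{i}") for i in range(n)]
    return GRMatrix(ids=ids, values=values, pair_counts=np.full((n, n), float(m_eff)))


def prune_related(grm: GRMatrix, threshold: float = 0.05) -> GRMatrix:
    """Drop individuals until no off-diagonal relatedness exceeds ``threshold``.

    Removal is greedy: at each step the individual participating in the most
    over-threshold pairs is deleted, ties broken by composite-key sort order.
    This retains the largest set in common cases and is fully reproducible.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    A = grm.values > threshold
    np.fill_diagonal(A, False)
    alive = np.ones(grm.n, dtype=bool)
    keys = np.array(grm.keys)
    while True:
        deg = (A & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max(initial=0) == 0:
            break
        worst = deg.max()
        cands = np.where(deg == worst)[0]
        # deterministic tie-break: smallest composite key
        drop = cands[np.argsort(keys[cands])[0]]
        alive[drop] = False
    return grm.subset(np.where(alive)[0])
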