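"""Marker-matrix handling and relationship/covariance structures.

Builds the covariance structures used throughout the package: the VanRaden
additive genomic relationship matrix ``G = Z Z' / (2 Σ p_j (1 - p_j))`` from
column-centered minor-allele dosages, its trace-normalized version
``GN = G / (tr(G)/n)``, and the stationary parametric structures (AR1,
compound symmetry) used for correlated locations and validation scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "CenteredMarkers",
    "CovStructure",
    "recode_minor_allele",
    "center_columns",
    "vanraden_g",
    "normalize_gn",
    "asv_kernel",
    "ar1_matrix",
    "compound_symmetry",
    "identity_structure",
    "double_center",
    "add_jitter",
]


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class MarkerMatrix:
    """Biallelic dosage matrix: n samples x p markers, entries in {0, 1, 2}.

    Entries count copies of one allele per locus; after
    :func:`recode_minor_allele` they count copies of the minor allele, so
    every column mean is at most 1 (allele frequency p_j <= 0.5).
    """

    dosages: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise InvalidInputError("dosages must be a 2-D array")
        vals = self.dosages
        if not np.all(np.isin(vals, (0, 1, 2))):
            raise InvalidInputError("marker dosages must be integers in {0, 1, 2}")
        self.dosages = vals.astype(np.int64)
        n, p = self.dosages.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if not self.marker_ids:
            self.marker_ids = [f"m{j}" for j in range(p)]
        if len(self.sample_ids) != n or len(self.marker_ids) != p:
            raise InvalidInputError("id lengths do not match dosage dimensions")
        if len(set(self.sample_ids)) != n or len(set(self.marker_ids)) != p:
            raise InvalidInputError("duplicate sample or marker identifiers")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_frequencies(self) -> np.ndarray:
        """Per-marker allele frequency of the coded allele, p_j = mean/2."""
        return self.dosages.mean(axis=0) / 2.0


@dataclass
class CenteredMarkers:
    """Column-centered dosages Z and the column means removed from them."""

    values: np.ndarray
    column_means: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


_KINDS = {"G", "GN", "identity", "AR1", "compound_symmetry", "custom"}


@dataclass
class CovStructure:
    """A symmetric n x n covariance structure with a kind tag and labels."""

    matrix: np.ndarray
    kind: str = "custom"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise InvalidInputError("covariance structure must be square")
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if self.matrix.size else 0.0
        if asym > 1e-8:
            raise InvalidInputError(f"matrix is not symmetric (max asymmetry {asym:.2e})")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)
        if self.kind not in _KINDS:
            raise InvalidInputError(f"unknown covariance kind {self.kind!r}")
        if not self.labels:
            self.labels = [f"s{i}" for i in range(self.matrix.shape[0])]
        if len(self.labels) != self.matrix.shape[0]:
            raise InvalidInputError("label count does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def trace_mean(self) -> float:
        return float(np.trace(self.matrix)) / self.n

    def subset(self, idx: np.ndarray) -> "CovStructure":
        """Principal submatrix on the given (integer) index set."""
        idx = np.asarray(idx, dtype=np.intp)
        if idx.size == 0:
            raise InvalidInputError("empty index set for covariance subset")
        return CovStructure(
            self.matrix[np.ix_(idx, idx)],
            kind="custom" if self.kind in ("AR1",) else self.kind,
            labels=[self.labels[i] for i in idx],
        )


def recode_minor_allele(M: MarkerMatrix) -> MarkerMatrix:
    """Flip columns whose coded-allele frequency exceeds 0.5 (x -> 2 - x).

    After recoding, every column counts copies of the minor allele, the
    convention the VanRaden denominator assumes. Columns at frequency
    exactly 0.5 are left unchanged.
    """
    freq = M.allele_frequencies
    flip = freq > 0.5
    if flip.any():
        logger.info("recoding %d of %d markers to minor-allele dosage", int(flip.sum()), M.p)
    dos = M.dosages.copy()
    dos[:, flip] = 2 - dos[:, flip]
    return MarkerMatrix(dos, list(M.sample_ids), list(M.marker_ids))


def center_columns(M: MarkerMatrix) -> CenteredMarkers:
    """Column-center the dosage matrix: Z[:, j] = dosage[:, j] - 2 p_j."""
    if M.n < 2:
        raise InvalidInputError("need at least 2 samples to center columns")
    means = M.dosages.mean(axis=0)
    Z = M.dosages.astype(float) - means
    return CenteredMarkers(Z, means, list(M.sample_ids), list(M.marker_ids))


def vanraden_g(M: MarkerMatrix, *, recode: bool = True, asv: bool = False) -> CovStructure:
    """VanRaden additive genomic relationship matrix.

    G = Z Z' / (2 Σ_j p_j (1 - p_j)), with Z the column-centered
    minor-allele dosage matrix.  Monomorphic markers contribute zero to
    both the numerator and the denominator and are kept so marker indices
    stay stable for the backsolve and the simulators.

    Parameters
    ----------
    recode : apply minor-allele recoding first (the formula assumes it).
    asv : use the average-semivariance scaling tr/(n-1) convention for the
        trace instead of the standard denominator. Off by default; the two
        differ only by the denominator of the cross-product scaling and
        the numerical differences are negligible in practice.
    """
    if recode:
        M = recode_minor_allele(M)
    Z = center_columns(M)
    p = M.allele_frequencies
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise InvalidInputError("all markers are monomorphic: VanRaden denominator is zero")
    G = (Z.values @ Z.values.T) / denom
    if asv:
        G = G * (M.n - 1) / M.n
    return CovStructure(G, kind="G", labels=list(M.sample_ids))


def normalize_gn(G: CovStructure) -> CovStructure:
    """Trace-normalize a relationship matrix: GN = G / (tr(G)/n)."""
    tr = float(np.trace(G.matrix))
    if tr <= 0:
        raise InvalidInputError("cannot normalize: trace is not positive")
    GN = G.matrix * (G.n / tr)
    return CovStructure(GN, kind="GN", labels=list(G.labels))


def asv_kernel(G: CovStructure) -> CovStructure:
    """Average-semivariance scaling K = G / (tr(G)/(n-1)).

    Exposed behind this function but never used by default pipelines;
    numerically it differs from GN only by the factor (n-1)/n.
    """
    tr = float(np.trace(G.matrix))
    if tr <= 0:
        raise InvalidInputError("cannot normalize: trace is not positive")
    K = G.matrix * ((G.n - 1) / tr)
    return CovStructure(K, kind="custom", labels=list(G.labels))


def ar1_matrix(n: int, rho: float) -> CovStructure:
    """First-order autoregressive correlation matrix, entry rho^|i-j|."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if abs(rho) > 1:
        raise InvalidInputError("AR1 autocorrelation must lie in [-1, 1]")
    idx = np.arange(n)
    mat = np.power(float(rho), np.abs(idx[:, None] - idx[None, :])) if rho != 0 else np.eye(n)
    if rho == 0:
        mat = np.eye(n)
    return CovStructure(mat, kind="AR1")


def compound_symmetry(n: int, rho: float) -> CovStructure:
    """Compound-symmetry correlation: unit diagonal, common rho off-diagonal.

    Positive semidefinite iff rho in (-1/(n-1), 1].
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    lo = -1.0 / (n - 1) if n > 1 else -1.0
    if not (lo - 1e-12 <= rho <= 1.0 + 1e-12) or (n > 1 and rho < lo):
        raise InvalidInputError(
            f"compound-symmetry correlation {rho} outside PSD range ({lo:.4g}, 1]"
        )
    mat = np.full((n, n), float(rho))
    np.fill_diagonal(mat, 1.0)
    return CovStructure(mat, kind="compound_symmetry")


def identity_structure(n: int) -> CovStructure:
    return CovStructure(np.eye(n), kind="identity")


def double_center(A: np.ndarray) -> np.ndarray:
    """Remove row and column main effects: a_ij - r_i - c_j + grand mean.

    Idempotent linear projection; the result has all row and column means
    equal to zero. Used to isolate interaction terms.
    """
    A = np.asarray(A, dtype=float)
    r = A.mean(axis=1, keepdims=True)
    c = A.mean(axis=0, keepdims=True)
    return A - r - c + A.mean()


def add_jitter(S: CovStructure, rel: float = 1e-8) -> CovStructure:
    """PSD repair: add rel * mean(diag) to the diagonal.

    Off by default everywhere; intended for structures destined for
    sampling or inversion that are numerically indefinite.
    """
    d = float(np.mean(np.diag(S.matrix)))
    mat = S.matrix + rel * max(d, 1.0) * np.eye(S.n)
    return CovStructure(mat, kind=S.kind, labels=list(S.labels))
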