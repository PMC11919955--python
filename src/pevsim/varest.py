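"""Additive-variance estimators and the unbiased validation reference.

Four ways of extracting the additive variance sigma2_a from a fitted
stage-2 model, plus the reference estimator used to judge them:

- ``vanraden``: the raw REML scaler sigma2_a* from a fit with K = G.
  Interpretable as a variance only if G had unit overall variance, which
  the standard centering does not guarantee.
- ``gn``: the REML scaler from a fit with the trace-normalized K = GN.
  Still biased: the trace mean ignores the off-diagonals.
- ``m2``: the quadratic form beta' Sigma_M beta over backsolved marker
  effects and the marker covariance matrix.  Equals the sample variance
  of the BLUPs, so shrinkage biases it downward.
- ``pev``: var(a_hat) + tr(PEV)/n.  The average prediction error
  variance compensates the BLUP shrinkage, making this the estimator of
  choice.
- ``unbiased_reference``: var(g_hat) - sigma2_eps, available only in the
  single-random-effect validation model, where the sample variance of the
  response minus the REML residual variance is unbiased for sigma2_a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lmm import GBLUPResults
from .relmat import CenteredMarkers, InvalidInputError

__all__ = [
    "VarianceEstimate",
    "estimate_vanraden",
    "estimate_gn",
    "estimate_m2",
    "estimate_pev",
    "unbiased_reference",
    "marker_covariance",
    "standardize_table",
]

_METHODS = {"vanraden", "gn", "m2", "pev", "unbiased_reference"}


@dataclass
class VarianceEstimate:
    """One additive-variance estimate with its method tag and breakdown."""

    method: str
    value: float
    components: dict = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise InvalidInputError(f"unknown estimation method {self.method!r}")


def _check_fit(fit: GBLUPResults, expected_kinds: tuple[str, ...], method: str):
    if not fit.converged:
        raise InvalidInputError(f"{method} estimator requires a converged fit")
    if fit.kind not in expected_kinds:
        raise InvalidInputError(
            f"{method} estimator expects a fit with K kind in {expected_kinds}, "
            f"got {fit.kind!r}")


def estimate_vanraden(fit: GBLUPResults) -> VarianceEstimate:
    """REML scaler from a K = G fit, read directly as the variance."""
    _check_fit(fit, ("G",), "vanraden")
    return VarianceEstimate("vanraden", float(fit.sigma2_a_star))


def estimate_gn(fit: GBLUPResults) -> VarianceEstimate:
    """REML scaler from a K = GN fit, read directly as the variance."""
    _check_fit(fit, ("GN",), "gn")
    return VarianceEstimate("gn", float(fit.sigma2_a_star))


def marker_covariance(Z: CenteredMarkers | np.ndarray, max_markers: int = 20_000) -> np.ndarray:
    """Covariance matrix between the marker columns of Z (n-1 denominator).

    Computed on demand only: the p x p result becomes memory-hungry for
    large marker panels (a warning is emitted above ``max_markers``).
    """
    Zm = Z.values if isinstance(Z, CenteredMarkers) else np.asarray(Z, dtype=float)
    n, p = Zm.shape
    if p > max_markers:
        warnings.warn(f"computing a {p} x {p} marker covariance matrix",
                      ResourceWarning, stacklevel=2)
    Zc = Zm - Zm.mean(axis=0)
    return (Zc.T @ Zc) / (n - 1)


def estimate_m2(beta: np.ndarray, Sigma_M: np.ndarray) -> VarianceEstimate:
    """Marker-effect quadratic form: sigma2_a = beta' Sigma_M beta."""
    beta = np.asarray(beta, dtype=float).ravel()
    Sigma_M = np.asarray(Sigma_M, dtype=float)
    if Sigma_M.shape != (beta.size, beta.size):
        raise InvalidInputError("beta and Sigma_M dimensions disagree")
    if np.max(np.abs(Sigma_M - Sigma_M.T)) > 1e-8:
        raise InvalidInputError("Sigma_M must be symmetric")
    value = float(beta @ Sigma_M @ beta)
    return VarianceEstimate("m2", value)


def estimate_pev(a_hat: np.ndarray, pev: np.ndarray) -> VarianceEstimate:
    """Shrinkage-corrected estimator: sum(a_hat^2)/n + tr(PEV)/n.

    The BLUP sample variance uses the n denominator because BLUPs are
    mean-centered (their population mean is known to be zero).
    """
    a_hat = np.asarray(a_hat, dtype=float).ravel()
    pev = np.asarray(pev, dtype=float)
    n = a_hat.size
    if pev.shape != (n, n):
        raise InvalidInputError("PEV matrix dimension does not match a_hat")
    sd = a_hat.std()
    if abs(a_hat.mean()) > 1e-6 * max(sd, 1e-12):
        raise InvalidInputError(
            "a_hat is not mean-centered; BLUPs from a correct model are")
    var_blup = float(np.sum(a_hat**2)) / n
    mean_pev = float(np.trace(pev)) / n
    return VarianceEstimate("pev", var_blup + mean_pev,
                            components={"var_blup": var_blup, "mean_pev": mean_pev})


def unbiased_reference(g_hat: np.ndarray, sigma2_eps: float) -> VarianceEstimate:
    """Validation reference: sample variance of g_hat minus sigma2_eps.

    May be negative (kept, flagged): the validation pipeline averages
    these values and truncation would bias it.
    """
    g_hat = np.asarray(g_hat, dtype=float).ravel()
    if g_hat.size < 2:
        raise InvalidInputError("need at least 2 genotypes")
    if sigma2_eps < 0:
        raise InvalidInputError("sigma2_eps must be non-negative")
    value = float(g_hat.var(ddof=1)) - float(sigma2_eps)
    flagged = value < 0
    if flagged:
        warnings.warn("unbiased reference is negative (noise exceeds signal)",
                      RuntimeWarning, stacklevel=2)
    est = VarianceEstimate("unbiased_reference", value)
    est.flagged = flagged
    return est


def standardize_table(estimates: dict[str, VarianceEstimate],
                      reference: VarianceEstimate) -> dict[str, float]:
    """Each estimate divided by the reference value (reference column = 1)."""
    if reference.value <= 0:
        raise InvalidInputError("reference variance must be positive to standardize")
    row = {"unbiased": 1.0}
    for name, est in estimates.items():
        row[name] = est.value / reference.value
    return row


def rmse_vs_reference(rows: list[dict[str, float]], references: list[float],
                      method: str) -> float:
    """Root-mean-square error of a method against the unbiased reference.

    Computed on the standardized scale then multiplied back by the
    reference, matching how comparison tables are presented.
    """
    devs = [(row[method] - 1.0) * ref for row, ref in zip(rows, references)]
    return float(np.sqrt(np.mean(np.square(devs))))
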