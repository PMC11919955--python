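"""Generalized standard errors and effective sample sizes for MVN vectors.

For X ~ MVN(mu, Sigma) with n components, the sample mean and sample
variance of a single realization are themselves random.  Their standard
errors (SEM and SEV) reduce to the familiar i.i.d. formulas
``SEM = sigma / sqrt(n)`` and ``SEV = sqrt(2) sigma^2 / sqrt(n - 1)`` only
when Sigma = sigma^2 I and the means are constant.  This module implements
the closed forms for arbitrary mean vectors and covariance structures:

    SEM      = sqrt(1' Sigma 1) / n
    Sigma1   = Sigma + SEM^2 1 1' - (row-mean broadcast both ways)
    Sigma2   = 2 Sigma1 ∘ Sigma1 + 4 Sigma1 ∘ (mu_c mu_c')
    SEV      = sqrt(1' Sigma2 1) / (n - 1)
    ESS_mu   = n tr(Sigma) / (1' Sigma 1)
    ESS_var  = 2 (tr(Sigma)/n)^2 (n-1)^2 / (1' Sigma2 1) + 1

where mu_c is the centered mean vector.  The effective sample sizes are
the i.i.d.-equivalent numbers of observations for estimating the mean and
the variance of the correlated vector; both are insensitive to rescaling
Sigma when the mean vector is zero.

Degenerate limits are signalled rather than raised: a perfectly
correlated Sigma gives ESS_mu = 1 and an infinite ESS_var (SEV = 0), and a
row-sum-zero Sigma (for example a VanRaden G) gives SEM = 0 with ESS_mu
undefined (returned as NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relmat import CovStructure, InvalidInputError

__all__ = [
    "MVNSpec",
    "ESSResult",
    "sem_iid",
    "sev_iid",
    "sigma2_bar",
    "sigma1_matrix",
    "sigma2_matrix",
    "generalized_sem",
    "generalized_sev",
    "ess_mu",
    "ess_var",
    "ess_summary",
    "empirical_se",
    "sample_mvn",
]

_TINY = 1e-10


@dataclass
class MVNSpec:
    """A multivariate normal specification: mean vector and covariance."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sig = self.sigma.matrix if isinstance(self.sigma, CovStructure) else self.sigma
        self.sigma = np.asarray(sig, dtype=float)
        if self.sigma.ndim != 2 or self.sigma.shape[0] != self.sigma.shape[1]:
            raise InvalidInputError("sigma must be square")
        if self.mu.shape[0] != self.sigma.shape[0]:
            raise InvalidInputError("mu and sigma dimensions disagree")
        if np.max(np.abs(self.sigma - self.sigma.T)) > 1e-8:
            raise InvalidInputError("sigma is not symmetric")
        self.sigma = 0.5 * (self.sigma + self.sigma.T)

    @property
    def n(self) -> int:
        return self.mu.shape[0]

    @classmethod
    def zero_mean(cls, sigma) -> "MVNSpec":
        sig = sigma.matrix if isinstance(sigma, CovStructure) else np.asarray(sigma)
        return cls(np.zeros(sig.shape[0]), sig)


@dataclass
class ESSResult:
    """SEM, SEV, trace-mean variance and effective sample sizes for one MVN."""

    sem: float
    sev: float
    sigma2_bar: float
    ess_mu: float  # NaN when 1' Sigma 1 = 0
    ess_var: float  # inf when 1' Sigma2 1 = 0 (SEV = 0)
    n: int


def sem_iid(sigma2: float, n: int) -> float:
    """Standard error of the mean of n i.i.d. observations: sqrt(sigma2/n)."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if sigma2 < 0:
        raise InvalidInputError("variance must be non-negative")
    return float(np.sqrt(sigma2 / n))

def sev_iid(sigma2: float, n: int) -> float:
    """Standard error of the sample variance of n i.i.d. normal observations."""
    if n < 2:
        raise InvalidInputError("n must be >= 2")
    if sigma2 < 0:
        raise InvalidInputError("variance must be non-negative")
    return float(np.sqrt(2.0) * sigma2 / np.sqrt(n - 1))


def sigma2_bar(spec: MVNSpec) -> float:
    """Trace-mean variance tr(Sigma)/n."""
    return float(np.trace(spec.sigma)) / spec.n


def sigma1_matrix(spec: MVNSpec) -> np.ndarray:
    """Covariance of the mean-centered vector X - Xbar.

    Sigma1[i,j] = Sigma[i,j] + SEM^2 - rowmean_i - rowmean_j; all row sums
    of the result are zero by construction.
    """
    S = spec.sigma
    n = spec.n
    sem2 = S.sum() / n**2
    r = S.sum(axis=1) / n
    return S + sem2 - r[:, None] - r[None, :]


def sigma2_matrix(sigma1: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Covariance of the squared centered deviations.

    Sigma2[i,j] = 2 Sigma1[i,j]^2 + 4 Sigma1[i,j] (mu_i - mubar)(mu_j - mubar).
    """
    sigma1 = np.asarray(sigma1, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if sigma1.shape[0] != mu.shape[0]:
        raise InvalidInputError("sigma1 and mu dimensions disagree")
    mc = mu - mu.mean()
    return 2.0 * sigma1**2 + 4.0 * sigma1 * np.outer(mc, mc)


def generalized_sem(spec: MVNSpec) -> float:
    """SEM for a correlated vector: sqrt(1' Sigma 1)/n (mean-independent)."""
    q = float(spec.sigma.sum())
    if q < -_TINY * max(1.0, abs(np.trace(spec.sigma))):
        raise InvalidInputError("1' Sigma 1 is negative: sigma is not PSD")
    return float(np.sqrt(max(q, 0.0))) / spec.n


def generalized_sev(spec: MVNSpec) -> float:
    """SEV for a correlated vector: sqrt(1' Sigma2 1)/(n - 1)."""
    if spec.n < 2:
        raise InvalidInputError("n must be >= 2")
    S2 = sigma2_matrix(sigma1_matrix(spec), spec.mu)
    q = float(S2.sum())
    return float(np.sqrt(max(q, 0.0))) / (spec.n - 1)


def ess_mu(spec: MVNSpec) -> float:
    """Effective sample size for the mean: n tr(Sigma) / (1' Sigma 1).

    Returns NaN when 1' Sigma 1 = 0 (perfect cancellation; the mean of the
    vector is a known constant and its ESS is undefined).
    """
    q = float(spec.sigma.sum())
    tr = float(np.trace(spec.sigma))
    if q <= _TINY * max(tr, 1.0):
        return float("nan")
    return tr / q * spec.n


def ess_var(spec: MVNSpec) -> float:
    """Effective sample size for the variance.

    ESS_var = 2 (tr(Sigma)/n)^2 (n-1)^2 / (1' Sigma2 1) + 1; returns +inf
    when the denominator vanishes (SEV = 0, e.g. perfect correlation).
    """
    if spec.n < 2:
        raise InvalidInputError("n must be >= 2")
    S2 = sigma2_matrix(sigma1_matrix(spec), spec.mu)
    q = float(S2.sum())
    s2b = sigma2_bar(spec)
    if q <= _TINY * max(s2b**2, 1.0):
        return float("inf")
    return 2.0 * s2b**2 * (spec.n - 1) ** 2 / q + 1.0


def ess_summary(spec: MVNSpec) -> ESSResult:
    """All closed-form quantities for one MVN specification."""
    return ESSResult(
        sem=generalized_sem(spec),
        sev=generalized_sev(spec) if spec.n >= 2 else float("nan"),
        sigma2_bar=sigma2_bar(spec),
        ess_mu=ess_mu(spec),
        ess_var=ess_var(spec) if spec.n >= 2 else float("nan"),
        n=spec.n,
    )


def expected_sample_variance(sigma: np.ndarray | CovStructure) -> float:
    """E[s^2] of one MVN draw: (tr(Sigma) - 1'Sigma 1/n) / (n - 1).

    Equals the trace of the double-centered covariance divided by n - 1;
    the target a simulation hits on average when a term is drawn from
    MVN(0, Sigma) without rescaling.
    """
    S = sigma.matrix if isinstance(sigma, CovStructure) else np.asarray(sigma, dtype=float)
    n = S.shape[0]
    if n < 2:
        raise InvalidInputError("n must be >= 2")
    return (float(np.trace(S)) - float(S.sum()) / n) / (n - 1)


def _sqrt_factor(sigma: np.ndarray) -> np.ndarray:
    """Eigendecomposition square root; tolerates PSD-but-singular Sigma."""
    w, V = np.linalg.eigh(sigma)
    wmax = float(w[-1]) if w.size else 0.0
    if w[0] < -1e-8 * max(wmax, 1.0):
        raise InvalidInputError("sigma is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def sample_mvn(spec: MVNSpec, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n_samples vectors from MVN(mu, Sigma); rows are samples.

    Uses an eigendecomposition square root so singular covariances
    (relationship matrices, all-ones limits) remain sampleable.
    """
    F = _sqrt_factor(spec.sigma)
    z = rng.standard_normal((n_samples, spec.n))
    return spec.mu + z @ F.T


def empirical_se(
    spec: MVNSpec,
    n_samples: int = 100_000,
    seed: int | np.random.Generator | None = 0,
    batch: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo SEM and SEV: sd of per-sample means and sample variances.

    Each drawn vector contributes one sample mean and one sample variance
    (n-1 denominator); the standard deviations of those two collections
    estimate SEM and SEV empirically.
    """
    if n_samples < 100:
        raise InvalidInputError("n_samples must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    F = _sqrt_factor(spec.sigma)
    step = batch or min(n_samples, 20_000)
    means = np.empty(n_samples)
    varis = np.empty(n_samples)
    done = 0
    while done < n_samples:
        k = min(step, n_samples - done)
        X = spec.mu + rng.standard_normal((k, spec.n)) @ F.T
        means[done : done + k] = X.mean(axis=1)
        varis[done : done + k] = X.var(axis=1, ddof=1)
        done += k
    return float(means.std(ddof=1)), float(varis.std(ddof=1))


def empirical_se_batched(
    spec: MVNSpec,
    n_samples: int = 10_000,
    n_batches: int = 10,
    seed: int | np.random.Generator | None = 0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Empirical (SEM, SEV) plus Monte-Carlo standard errors by batching.

    Splits the draws into ``n_batches`` independent batches, computes the
    empirical SEM/SEV per batch, and reports the across-batch standard
    error of each; used when a "within k Monte-Carlo SEs" comparison
    against the closed forms is needed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per = max(n_samples // n_batches, 100)
    sems, sevs = [], []
    for _ in range(n_batches):
        se_m, se_v = empirical_se(spec, per, rng)
        sems.append(se_m)
        sevs.append(se_v)
    sems = np.array(sems)
    sevs = np.array(sevs)
    mc_m = float(sems.std(ddof=1) / np.sqrt(n_batches))
    mc_v = float(sevs.std(ddof=1) / np.sqrt(n_batches))
    return (float(sems.mean()), mc_m), (float(sevs.mean()), mc_v)
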