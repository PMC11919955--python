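"""Field-trial simulators: the MVN, Fixed and ESS strategies.

All three simulate the same multi-location RCBD trial model
``y = L + Block(L) + a + aL + e`` over a balanced design and differ only
in how the per-term variances are controlled:

- **MVN**: every term is drawn from its assumed multivariate normal
  distribution using REML-style scaling factors.  No correction is
  applied, so the realized sample variances drift away from the targets
  whenever the covariance structures (G, correlated locations) are not
  unit-variance — the failure mode this package quantifies.
- **Fixed**: effects are simulated at the marker level (gamma-distributed
  QTL effects with random signs), then each term is rescaled so its
  realized standard deviation equals the target exactly.  Unbiased but
  ignores sampling variance: every repetition has identical variances.
- **ESS**: like Fixed, but each term's squared scaling target is drawn
  from a gamma distribution with mean equal to the target variance and
  standard deviation equal to the term's standard error of the variance
  (SEV), computed from the generalized effective-sample-size equations
  for correlated terms and from the i.i.d. formula for blocks and
  residuals.  Reps fluctuate around the target with the theoretically
  correct dispersion.

Conventions: sample statistics use the n-1 denominator throughout;
Kronecker-structured interaction effects are ordered genotype-fastest
within location (the vec of the genotypes x locations matrix taken
column by column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import esstats
from .esstats import MVNSpec, sample_mvn
from .relmat import CovStructure, InvalidInputError, double_center
from .relmat import MarkerMatrix, normalize_gn

__all__ = [
    "TrialDesign",
    "TargetVariances",
    "SimulationResult",
    "simulate_mvn",
    "simulate_fixed",
    "simulate_ess",
    "sample_marker_effects",
    "scale_to_target",
    "simulate_axl",
    "location_effects_from_axl",
    "sample_variance_gamma",
    "ess_term_sevs",
]

TERMS = ("location", "block", "additive", "axl", "residual")


@dataclass
class TrialDesign:
    """Balanced RCBD layout: every genotype in every block of every location."""

    n_genotypes: int = 50
    n_locations: int = 5
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_locations, self.n_blocks) < 1:
            raise InvalidInputError("design dimensions must be positive")

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * self.n_locations * self.n_blocks

    def layout(self) -> pd.DataFrame:
        """Plot table with genotype / location / block codes."""
        g = np.arange(self.n_genotypes)
        rows = []
        for loc in range(self.n_locations):
            for blk in range(self.n_blocks):
                rows.append(pd.DataFrame({
                    "genotype": [f"g{i}" for i in g],
                    "location": f"L{loc}",
                    "block": f"B{blk}",
                    "gi": g, "li": loc, "bi": blk}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class TargetVariances:
    """Per-term target variances (and MVN-strategy scaling factors)."""

    sigma2_L: float = 1.0
    sigma2_Block: float = 0.25
    sigma2_a: float = 1.0
    sigma2_aL: float = 0.5
    sigma2_eps: float = 1.0
    # REML-style scalers for the MVN strategy; default to the plain targets
    # (the common practice the MVN strategy embodies)
    sigma2_L_star: float | None = None
    sigma2_a_star: float | None = None
    sigma2_aL_star: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma2_L", "sigma2_Block", "sigma2_a", "sigma2_aL", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    def scaler(self, which: str) -> float:
        star = getattr(self, f"sigma2_{which}_star")
        return float(star if star is not None else getattr(self, f"sigma2_{which}"))

    def target(self, term: str) -> float:
        return {
            "location": self.sigma2_L, "block": self.sigma2_Block,
            "additive": self.sigma2_a, "axl": self.sigma2_aL,
            "residual": self.sigma2_eps}[term]


@dataclass
class SimulationResult:
    """Effects, phenotypes and realized variances for one simulation rep."""

    strategy: str
    effects: dict  # location (L,), block (L,B), additive (n,), axl (n,L), residual (plots,)
    phenotypes: pd.DataFrame  # long format genotype/location/block/value
    realized_variances: dict
    sampled_targets: dict = field(default_factory=dict)  # ESS strategy only
    seed: int | None = None

    def phenotype_vector(self) -> np.ndarray:
        return self.phenotypes["value"].to_numpy()


def _var(x: np.ndarray) -> float:
    return float(np.var(np.asarray(x, dtype=float).ravel(), ddof=1))


def _realized(effects: dict, design: TrialDesign) -> dict:
    block = effects["block"]
    eps = effects["residual"].reshape(design.n_locations, -1)
    return {
        "location": _var(effects["location"]),
        "block": float(np.mean([_var(block[l]) for l in range(design.n_locations)])),
        "additive": _var(effects["additive"]),
        "axl": _var(effects["axl"]),
        "residual": float(np.mean([_var(eps[l]) for l in range(design.n_locations)])),
    }


def _assemble(strategy: str, effects: dict, design: TrialDesign,
              sampled: dict | None = None, seed: int | None = None) -> SimulationResult:
    lay = design.layout()
    gi = lay["gi"].to_numpy()
    li = lay["li"].to_numpy()
    bi = lay["bi"].to_numpy()
    y = (effects["location"][li] + effects["block"][li, bi]
         + effects["additive"][gi] + effects["axl"][gi, li] + effects["residual"])
    pheno = lay[["genotype", "location", "block"]].copy()
    pheno["value"] = y
    return SimulationResult(strategy, effects, pheno, _realized(effects, design),
                            sampled or {}, seed)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# MVN strategy
# ---------------------------------------------------------------------------


def simulate_mvn(targets: TargetVariances, G: CovStructure, Ke: CovStructure,
                 design: TrialDesign, seed=None) -> SimulationResult:
    """Draw every term from its assumed distribution (no rescaling).

    L ~ MVN(0, Ke s2L*), Block ~ iid N(0, s2B), a ~ MVN(0, G s2a*),
    aL ~ MVN(0, (Ke x G) s2aL*) genotype-fastest, e ~ iid N(0, s2e).
    """
    if G.n != design.n_genotypes:
        raise InvalidInputError("G dimension does not match the design")
    if Ke.n != design.n_locations:
        raise InvalidInputError("Ke dimension does not match the design")
    rng = _rng(seed)
    nl, nb, ng = design.n_locations, design.n_blocks, design.n_genotypes
    s2L, s2a, s2aL = (targets.scaler(w) for w in ("L", "a", "aL"))
    L = sample_mvn(MVNSpec.zero_mean(Ke.matrix * s2L), 1, rng)[0] if s2L > 0 else np.zeros(nl)
    block = rng.normal(0.0, np.sqrt(targets.sigma2_Block), size=(nl, nb))
    a = sample_mvn(MVNSpec.zero_mean(G.matrix * s2a), 1, rng)[0] if s2a > 0 else np.zeros(ng)
    if s2aL > 0:
        kron = np.kron(Ke.matrix, G.matrix) * s2aL
        axl = sample_mvn(MVNSpec.zero_mean(kron), 1, rng)[0].reshape(nl, ng).T
    else:
        axl = np.zeros((ng, nl))
    eps = rng.normal(0.0, np.sqrt(targets.sigma2_eps), size=design.n_plots)
    effects = {"location": L, "block": block, "additive": a, "axl": axl, "residual": eps}
    return _assemble("mvn", effects, design, seed=None)


# ---------------------------------------------------------------------------
# Marker-level building blocks (Fixed / ESS strategies)
# ---------------------------------------------------------------------------


def sample_marker_effects(n_qtl: int, shape: float = 0.4, scale: float = 1.66,
                          seed=None) -> np.ndarray:
    """Gamma-distributed QTL effect magnitudes with independent fair signs."""
    if n_qtl < 1:
        raise InvalidInputError("n_qtl must be >= 1")
    if shape <= 0 or scale <= 0:
        raise InvalidInputError("gamma shape and scale must be positive")
    rng = _rng(seed)
    mag = rng.gamma(shape, scale, size=n_qtl)
    signs = rng.choice((-1.0, 1.0), size=n_qtl)
    return mag * signs


def scale_to_target(values: np.ndarray, sigma_target: float) -> np.ndarray:
    """Rescale so the sample standard deviation equals sigma_target exactly."""
    values = np.asarray(values, dtype=float)
    if sigma_target < 0:
        raise InvalidInputError("target standard deviation must be non-negative")
    if sigma_target == 0:
        return np.zeros_like(values)
    sd = float(np.std(values, ddof=1))
    if sd <= 0:
        raise InvalidInputError("cannot scale a constant array to a positive target")
    return values * (sigma_target / sd)


def simulate_axl(Ma: np.ndarray, n_cov: int, Ke: CovStructure, seed=None,
                 return_raw: bool = False):
    """Marker-level genotype-by-location interaction AxL* = Ma B_aL L_cov.

    B_aL (p x n_cov) holds standard-normal interaction intensities between
    QTL and environmental covariates; each of the n_cov covariate rows of
    L_cov is drawn from MVN(0, Ke).  The returned matrix is
    double-centered so only interaction variation remains; pass
    ``return_raw=True`` to also obtain the pre-centering matrix (its
    column means carry the induced location main effects).
    """
    Ma = np.asarray(Ma, dtype=float)
    if n_cov < 1:
        raise InvalidInputError("n_cov must be >= 1")
    rng = _rng(seed)
    p = Ma.shape[1]
    B = rng.standard_normal((p, n_cov))
    Lcov = sample_mvn(MVNSpec.zero_mean(Ke.matrix), n_cov, rng)  # n_cov x L
    raw = Ma @ B @ Lcov
    centered = double_center(raw)
    return (centered, raw) if return_raw else centered


def location_effects_from_axl(AxL_star: np.ndarray) -> np.ndarray:
    """Location main effects induced by the raw interaction matrix.

    One value per location: the column mean of the pre-centering AxL*.
    A double-centered input yields the zero vector (degenerate, flagged).
    """
    AxL_star = np.asarray(AxL_star, dtype=float)
    out = AxL_star.mean(axis=0)
    if np.allclose(out, 0.0, atol=1e-12):
        warnings.warn("AxL* appears double-centered: induced location effects "
                      "are zero", RuntimeWarning, stacklevel=2)
    return out


def sample_variance_gamma(sigma2: float, sev: float, seed=None) -> float:
    """One sample variance drawn from Gamma(mean=sigma2, sd=sev).

    Scale theta = SEV^2 / sigma2 and shape k = sigma2^2 / SEV^2, so that
    theta k = sigma2 and theta^2 k = SEV^2.  sev = 0 returns sigma2
    exactly (degenerate distribution).
    """
    if sigma2 < 0 or sev < 0:
        raise InvalidInputError("sigma2 and sev must be non-negative")
    if sev == 0 or sigma2 == 0:
        return float(sigma2)
    rng = _rng(seed)
    theta = sev**2 / sigma2
    k = sigma2**2 / sev**2
    return float(rng.gamma(k, theta))


def _marker_effects_pipeline(targets_sd: dict, M_subset: MarkerMatrix,
                             Ke: CovStructure, design: TrialDesign, n_qtl: int,
                             rng: np.random.Generator,
                             gamma_shape: float, gamma_scale: float, n_cov: int):
    """Shared Fixed/ESS machinery: marker-level effects scaled to target sds."""
    ng, nl, nb = design.n_genotypes, design.n_locations, design.n_blocks
    if M_subset.n != ng:
        raise InvalidInputError("marker matrix rows do not match the design")
    if n_qtl > M_subset.p:
        raise InvalidInputError("n_qtl exceeds the number of markers")
    if Ke.n != nl:
        raise InvalidInputError("Ke dimension does not match the design")
    qtl = rng.choice(M_subset.p, size=n_qtl, replace=False)
    Mq = M_subset.dosages[:, qtl].astype(float)
    beta_star = sample_marker_effects(n_qtl, gamma_shape, gamma_scale, rng)
    a_star = Mq @ beta_star
    sd_a_star = float(np.std(a_star, ddof=1))
    if sd_a_star <= 0:
        raise InvalidInputError("degenerate marker panel: additive values constant")
    beta = beta_star * (targets_sd["additive"] / sd_a_star)
    a = Mq @ beta
    Ma = Mq * beta
    axl_c, axl_raw = simulate_axl(Ma, n_cov, Ke, rng, return_raw=True)
    axl = scale_to_target(axl_c, targets_sd["axl"]) if targets_sd["axl"] > 0 \
        else np.zeros_like(axl_c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        L_star = location_effects_from_axl(axl_raw)
    if float(np.std(L_star, ddof=1)) <= 0:
        L_star = rng.standard_normal(nl)  # degenerate fallback, then scaled
    L = scale_to_target(L_star, targets_sd["location"])
    block = np.zeros((nl, nb))
    eps = np.zeros(design.n_plots)
    per_loc = ng * nb
    for l in range(nl):
        block[l] = scale_to_target(rng.standard_normal(nb), targets_sd[("block", l)])
        eps[l * per_loc:(l + 1) * per_loc] = scale_to_target(
            rng.standard_normal(per_loc), targets_sd[("residual", l)])
    return {"location": L, "block": block, "additive": a, "axl": axl,
            "residual": eps, "beta": beta, "qtl": qtl}


def simulate_fixed(targets: TargetVariances, M_subset: MarkerMatrix,
                   Ke: CovStructure, design: TrialDesign, n_qtl: int = 2500,
                   seed=None, gamma_shape: float = 0.4, gamma_scale: float = 1.66,
                   n_cov: int = 100) -> SimulationResult:
    """Marker-based simulation with every term scaled to its target exactly."""
    rng = _rng(seed)
    sds = {"additive": np.sqrt(targets.sigma2_a), "axl": np.sqrt(targets.sigma2_aL),
           "location": np.sqrt(targets.sigma2_L)}
    for l in range(design.n_locations):
        sds[("block", l)] = np.sqrt(targets.sigma2_Block)
        sds[("residual", l)] = np.sqrt(targets.sigma2_eps)
    eff = _marker_effects_pipeline(sds, M_subset, Ke, design, n_qtl, rng,
                                   gamma_shape, gamma_scale, n_cov)
    extra = {"beta": eff.pop("beta"), "qtl": eff.pop("qtl")}
    out = _assemble("fixed", eff, design)
    out.effects.update(extra)
    return out


def ess_term_sevs(targets: TargetVariances, GN: CovStructure, Ke: CovStructure,
                  design: TrialDesign) -> dict:
    """Per-term SEV values used by the ESS strategy.

    Correlated terms use the generalized closed form with the term's
    assumed covariance (GN-based for genetic terms, so the trace mean
    equals the target); i.i.d. blocks and residuals use the classical
    formula with n equal to the number of draws being rescaled.
    """
    GNn = normalize_gn(GN) if abs(GN.trace_mean - 1.0) > 1e-8 else GN
    ng, nl, nb = design.n_genotypes, design.n_locations, design.n_blocks
    sev = {}
    sev["additive"] = esstats.generalized_sev(
        MVNSpec.zero_mean(GNn.matrix * targets.sigma2_a)) if targets.sigma2_a > 0 else 0.0
    sev["location"] = esstats.generalized_sev(
        MVNSpec.zero_mean(Ke.matrix * targets.sigma2_L)) if targets.sigma2_L > 0 else 0.0
    if targets.sigma2_aL > 0:
        kron = np.kron(Ke.matrix, GNn.matrix) * targets.sigma2_aL
        sev["axl"] = esstats.generalized_sev(MVNSpec.zero_mean(kron))
    else:
        sev["axl"] = 0.0
    sev["block"] = esstats.sev_iid(targets.sigma2_Block, nb) if nb >= 2 else 0.0
    sev["residual"] = esstats.sev_iid(targets.sigma2_eps, ng * nb)
    return sev


def simulate_ess(targets: TargetVariances, M_subset: MarkerMatrix,
                 G_for_sev: CovStructure, Ke: CovStructure, design: TrialDesign,
                 n_qtl: int = 2500, seed=None, gamma_shape: float = 0.4,
                 gamma_scale: float = 1.66, n_cov: int = 100,
                 sevs: dict | None = None) -> SimulationResult:
    """Marker-based simulation with gamma-sampled per-term variances.

    Each term's realized variance equals a draw s2 ~ Gamma(mean=target,
    sd=SEV) exactly; across repetitions the per-term variances are
    centered on the target with dispersion SEV.  Blocks and residuals
    draw one s2 per location independently.  A term whose SEV is zero
    (perfect correlation, or a zero target) degenerates to the Fixed
    behaviour with a warning.
    """
    rng = _rng(seed)
    if sevs is None:
        sevs = ess_term_sevs(targets, G_for_sev, Ke, design)
    for term, s in sevs.items():
        if s == 0.0 and targets.target(term if isinstance(term, str) else term[0]) > 0:
            warnings.warn(f"SEV for term {term!r} is zero: variance held fixed",
                          RuntimeWarning, stacklevel=2)
    sampled = {}
    sds = {}
    for term in ("additive", "axl", "location"):
        s2 = sample_variance_gamma(targets.target(term), sevs[term], rng)
        sampled[term] = s2
        sds[term] = np.sqrt(s2)
    for l in range(design.n_locations):
        s2b = sample_variance_gamma(targets.sigma2_Block, sevs["block"], rng)
        s2e = sample_variance_gamma(targets.sigma2_eps, sevs["residual"], rng)
        sampled[("block", l)] = s2b
        sampled[("residual", l)] = s2e
        sds[("block", l)] = np.sqrt(s2b)
        sds[("residual", l)] = np.sqrt(s2e)
    eff = _marker_effects_pipeline(sds, M_subset, Ke, design, n_qtl, rng,
                                   gamma_shape, gamma_scale, n_cov)
    extra = {"beta": eff.pop("beta"), "qtl": eff.pop("qtl")}
    out = _assemble("ess", eff, design, sampled=sampled)
    out.effects.update(extra)
    return out
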