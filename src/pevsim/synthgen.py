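"""Synthetic genotype and phenotype generation with known ground truth.

Produces marker panels that emulate the two population archetypes the
estimators must handle — fully inbred lines with strong structure and
linkage disequilibrium (LD) versus outbred populations near
Hardy-Weinberg proportions with weak structure — and phenotypes whose
per-term variance components are known exactly, so every estimator can be
validated without external data.

LD is induced with a Gaussian copula: latent haplotype values follow an
AR1 process within marker blocks, so adjacent loci within a block are
correlated while blocks are independent.  Population structure comes from
subpopulation-specific allele frequencies scattered around a common base
frequency.  Heterozygosity is controlled by an inbreeding mixture: with
probability ``inbreeding`` an individual's two haplotypes are identical
copies (no heterozygous calls), otherwise they are drawn independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .relmat import InvalidInputError, MarkerMatrix
from .simkit import (SimulationResult, TargetVariances, TrialDesign,
                     simulate_fixed)

__all__ = [
    "PopulationConfig",
    "GroundTruth",
    "generate_genotypes",
    "generate_trial",
    "drop_observations",
]


@dataclass
class PopulationConfig:
    """Knobs for the synthetic population.

    divergence is the standard deviation of subpopulation allele
    frequencies around the common base frequency (0 = panmictic);
    inbreeding in [0, 1] interpolates between outbred (0, spruce-like)
    and fully inbred (1, oat-like); ld_decay in [0, 1) is the latent
    correlation between adjacent loci within an LD block.
    """

    n_individuals: int = 200
    n_markers: int = 500
    n_subpops: int = 3
    divergence: float = 0.15
    inbreeding: float = 1.0
    ld_block_size: int = 20
    ld_decay: float = 0.9
    base_freq_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if not (0.0 <= self.inbreeding <= 1.0):
            raise InvalidInputError("inbreeding must lie in [0, 1]")
        if not (0.0 <= self.ld_decay < 1.0):
            raise InvalidInputError("ld_decay must lie in [0, 1)")
        if self.divergence < 0:
            raise InvalidInputError("divergence must be non-negative")
        if min(self.n_individuals, self.n_markers, self.n_subpops,
               self.ld_block_size) < 1:
            raise InvalidInputError("counts must be positive")


@dataclass
class GroundTruth:
    """True effects and variance components behind a generated trial."""

    true_beta: np.ndarray
    qtl_indices: np.ndarray
    true_a: np.ndarray
    variance_components: dict  # per-term target variances used
    var_a_n: float  # n-denominator variance of true_a
    var_a_n1: float  # (n-1)-denominator variance of true_a


def _latent_ar1(rng: np.random.Generator, n: int, p: int, block: int,
                rho: float) -> np.ndarray:
    """Latent Gaussians with AR1(rho) correlation within consecutive blocks."""
    z = np.empty((n, p))
    start = 0
    while start < p:
        width = min(block, p - start)
        e = rng.standard_normal((n, width))
        z[:, start] = e[:, 0]
        for j in range(1, width):
            z[:, start + j] = rho * z[:, start + j - 1] + np.sqrt(1 - rho**2) * e[:, j]
        start += width
    return z


def generate_genotypes(config: PopulationConfig, seed=None) -> MarkerMatrix:
    """Draw a biallelic dosage matrix under the configured population model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, p = config.n_individuals, config.n_markers
    lo, hi = config.base_freq_range
    base = rng.uniform(lo, hi, size=p)
    freqs = np.clip(base[None, :] + rng.normal(0.0, config.divergence,
                                               size=(config.n_subpops, p)),
                    0.01, 0.99)
    subpop = np.repeat(np.arange(config.n_subpops),
                       int(np.ceil(n / config.n_subpops)))[:n]
    thresh = norm.ppf(freqs[subpop])  # n x p: latent < thresh -> carry allele
    h1 = (_latent_ar1(rng, n, p, config.ld_block_size, config.ld_decay)
          < thresh).astype(np.int64)
    h2 = (_latent_ar1(rng, n, p, config.ld_block_size, config.ld_decay)
          < thresh).astype(np.int64)
    selfed = rng.random(n) < config.inbreeding
    h2[selfed] = h1[selfed]
    # sample labels match the trial layout's genotype labels
    return MarkerMatrix(h1 + h2, sample_ids=[f"g{i}" for i in range(n)])


def generate_trial(M: MarkerMatrix, targets: TargetVariances, design: TrialDesign,
                   seed=None, n_qtl: int | None = None, Ke=None,
                   ) -> tuple[pd.DataFrame, GroundTruth, SimulationResult]:
    """Simulate a trial over M with exactly known variance components.

    Reuses the Fixed marker-level machinery, so every per-term realized
    variance equals its target exactly and the additive architecture
    (gamma QTL effects, LD between markers) is genuinely marker-driven.
    Returns the long-format phenotype table, the ground truth, and the
    full simulation result.
    """
    from .relmat import compound_symmetry
    if Ke is None:
        Ke = compound_symmetry(design.n_locations, 0.3)
    if n_qtl is None:
        n_qtl = min(2500, M.p)
    sim = simulate_fixed(targets, M, Ke, design, n_qtl=n_qtl, seed=seed)
    a = sim.effects["additive"]
    truth = GroundTruth(
        true_beta=sim.effects["beta"],
        qtl_indices=sim.effects["qtl"],
        true_a=a,
        variance_components={t: targets.target(t) for t in
                             ("location", "block", "additive", "axl", "residual")},
        var_a_n=float(np.var(a, ddof=0)),
        var_a_n1=float(np.var(a, ddof=1)),
    )
    return sim.phenotypes, truth, sim


def drop_observations(phenotypes: pd.DataFrame, fraction: float, seed=None,
                      location: str = "location") -> pd.DataFrame:
    """Randomly discard a fraction of observations within each location.

    Stratified by location: each location keeps ceil((1 - fraction) * n)
    of its rows.  Genotypes losing all observations are allowed but
    reported via a ``dropped_genotypes`` DataFrame attribute.
    """
    if not (0.0 <= fraction < 1.0):
        raise InvalidInputError("fraction must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fraction == 0.0:
        out = phenotypes.copy()
        out.attrs["dropped_genotypes"] = []
        return out
    kept = []
    for _, sub in phenotypes.groupby(location, sort=False):
        n_keep = int(np.ceil((1.0 - fraction) * len(sub)))
        idx = rng.choice(sub.index.to_numpy(), size=n_keep, replace=False)
        kept.append(phenotypes.loc[np.sort(idx)])
    out = pd.concat(kept).sort_index()
    if "genotype" in phenotypes.columns:
        before = set(phenotypes["genotype"])
        after = set(out["genotype"])
        out.attrs["dropped_genotypes"] = sorted(before - after)
    return out
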