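import numpy as np
import pytest

from pevsim.relmat import MarkerMatrix, compound_symmetry
from pevsim.simkit import TargetVariances, TrialDesign
from pevsim.synthgen import PopulationConfig, generate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_markers():
    """Tiny hand-written marker matrix (4 samples x 3 markers)."""
    return MarkerMatrix(
        [[0, 2, 1],
         [1, 2, 0],
         [2, 0, 1],
         [0, 0, 0]],
        sample_ids=["a", "b", "c", "d"],
        marker_ids=["m1", "m2", "m3"],
    )


@pytest.fixture(scope="session")
def ld_markers():
    """Inbred, structured, LD-blocked marker panel (60 x 300)."""
    pop = PopulationConfig(n_individuals=60, n_markers=300)
    return generate_genotypes(pop, seed=7)


@pytest.fixture
def trial_design():
    return TrialDesign(n_genotypes=60, n_locations=2, n_blocks=3)


@pytest.fixture
def targets():
    return TargetVariances(sigma2_L=1.0, sigma2_Block=0.25, sigma2_a=1.0,
                           sigma2_aL=0.25, sigma2_eps=6.0)


@pytest.fixture
def ke5():
    return compound_symmetry(5, 0.3)
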