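import numpy as np
import pytest

from meliapop.markers import GenotypeTable
from meliapop.simulate import (GardenSimConfig, MarkerSimConfig,
                               simulate_common_garden, simulate_markers)


@pytest.fixture(scope="session")
def island_genotypes():
    """Moderate island-model dataset: 8 pops, 15 loci, 12 diploids/pop."""
    cfg = MarkerSimConfig(n_pops=8, n_loci=15, n_per_pop=12, target_fst=0.086,
                          seed=11)
    gt, truth = simulate_markers(cfg)
    return gt, truth


@pytest.fixture(scope="session")
def garden_table():
    """Balanced mid-size garden: 8 provenances x 5 families x 5 blocks x 3."""
    cfg = GardenSimConfig(n_prov=8, families_per_prov=5, n_blocks=5,
                          n_per_family_block=3, var_provenance=0.5,
                          var_family=0.0625, var_residual=1.0,
                          block_effects=list(np.linspace(-0.5, 0.5, 5)),
                          seed=21)
    tt, truth = simulate_common_garden(cfg)
    return tt, truth, cfg


@pytest.fixture
def tiny_gt():
    """Hand-sized 2-population, 2-locus table for formula oracles."""
    individuals = [f"i{k}" for k in range(8)]
    populations = np.array(["A"] * 4 + ["B"] * 4)
    loci = ["L1", "L2"]
    alleles = np.array([
        [[1, 1], [1, 2]],
        [[1, 2], [2, 2]],
        [[1, 1], [1, 1]],
        [[1, 2], [1, 2]],
        [[2, 2], [2, 3]],
        [[1, 2], [3, 3]],
        [[2, 2], [2, 2]],
        [[2, 2], [2, 3]],
    ])
    return GenotypeTable(individuals, populations, loci, alleles)
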