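"""Shared fixtures: small synthetic populations generated at test time."""

import numpy as np
import pytest

from dotox import scan, synthetic
from dotox.containers import TrueQtlSpec


@pytest.fixture(scope="session")
def founders_small():
    """4 chromosomes x 12 markers, private interval on chr 3."""
    return synthetic.simulate_founder_genomes(
        n_chromosomes=4,
        markers_per_chromosome=12,
        private_interval=(3, 30.0, 60.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def pop_small(founders_small):
    return synthetic.simulate_do_population(founders_small, 40, generation=8, seed=12)


@pytest.fixture(scope="session")
def truth_small(founders_small, pop_small):
    return synthetic.true_dosages(pop_small, founders_small)


@pytest.fixture(scope="session")
def kinship_small(truth_small):
    return scan.kinship_from_dosages(truth_small)


@pytest.fixture(scope="session")
def founders_default():
    """Study-condition genome: 10 chromosomes x 30 markers, chr 10 interval."""
    return synthetic.simulate_founder_genomes(seed=21)


@pytest.fixture(scope="session")
def qtl_default():
    return TrueQtlSpec(chromosome=10, position_mb=31.87, focal_founder="F")
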