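import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ssrscape.simulate import SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A small (600 kb) synthetic genome with ground truth, shared per session."""
    spec = SyntheticSpec(
        n_chromosomes=2,
        chromosome_length=300_000,
        genes_per_chromosome=10,
        n_ltr=10,
        ltr_ages_mya=(0.05, 0.15, 0.35, 0.55, 0.75),
    )
    return generate_genome(spec, seed=20240917)


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
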