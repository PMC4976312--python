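import numpy as np
import pytest

from nsfcnv import defaults
from nsfcnv.haplotypes import IndividualGenotype
from nsfcnv.synthetic import SimulationConfig


@pytest.fixture
def reference_table():
    """The nine-haplotype reference frequency table (normalized)."""
    return defaults.default_haplotype_table()


@pytest.fixture
def small_cohort():
    """Four unphased individuals with genuine phase/partition ambiguity."""
    return [
        IndividualGenotype("s1", (("A", "A"),), 2),
        IndividualGenotype("s2", (("A", "A"),), 2),
        IndividualGenotype("s3", (("A", "G"),), 3),
        IndividualGenotype("s4", (("G", "G"),), 4),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20160808)


def make_config(**kwargs) -> SimulationConfig:
    kwargs.setdefault("seed", 20160808)
    return SimulationConfig(**kwargs)
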