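import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from dcm_phenolink.linkage import Individual, Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(20200914)


@pytest.fixture
def multiplex_pedigree():
    """Three-generation multiplex family: one founder couple, four sibships."""
    inds = [
        Individual("A1", affection="unknown", sex="male"),
        Individual("A2", affection="unknown", sex="female"),
    ]
    for i in range(1, 5):
        inds.append(Individual(f"B{i}", "A1", "A2", "male" if i % 2 else "female", "unknown"))
        inds.append(Individual(f"S{i}", affection="unknown", sex="female" if i % 2 else "male"))
        for j in range(1, 4):
            f, m = (f"B{i}", f"S{i}") if i % 2 else (f"S{i}", f"B{i}")
            inds.append(Individual(f"C{i}{j}", f, m, "unknown", "unknown"))
    return Pedigree(inds)


@pytest.fixture
def cousin_loop_pedigree():
    """Nine-member family in which two first cousins marry (consanguinity loop)."""
    return Pedigree(
        [
            Individual("I1", affection="unknown", sex="male"),
            Individual("I2", affection="unknown", sex="female"),
            Individual("I3", "I1", "I2", "male", "unknown"),
            Individual("I4", "I1", "I2", "female", "unknown"),
            Individual("I5", affection="unknown", sex="female"),
            Individual("I6", affection="unknown", sex="male"),
            Individual("I7", "I3", "I5", "male", "unknown"),
            Individual("I8", "I6", "I4", "female", "unknown"),
            Individual("I9", "I7", "I8", sex="male", affection="affected"),
        ]
    )
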