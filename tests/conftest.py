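import numpy as np
import pytest

from kfvmotif import PFM
from kfvmotif.synthetic import random_pfm


@pytest.fixture
def rng():
    return np.random.default_rng(20100120)


@pytest.fixture
def pfm_acgt():
    """PFM of the single sequence ACGT: deterministic columns."""
    return PFM(id="acgt", counts=[[1, 0, 0, 0],
                                  [0, 1, 0, 0],
                                  [0, 0, 1, 0],
                                  [0, 0, 0, 1]])


@pytest.fixture
def random_pfms(rng):
    return [random_pfm(rng, id=f"pfm{i:02d}") for i in range(12)]
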