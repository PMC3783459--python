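import numpy as np
import pytest

from hapstruct.dataio import Alignment, SampleRecord
from hapstruct.synthetic import table2_fixture


@pytest.fixture(scope="session")
def spinner():
    """The published 37-haplotype table with synthetic stand-in sequences."""
    return table2_fixture()


@pytest.fixture
def tiny_alignment():
    """4 sequences of length 10, 2 populations."""
    return Alignment(
        [
            SampleRecord("s1", "north", "ACGTACGTAC"),
            SampleRecord("s2", "north", "ACGTACGTAC"),
            SampleRecord("s3", "south", "ACGTACGTAT"),
            SampleRecord("s4", "south", "ACGTACGTAC"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
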