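import numpy as np
import pytest

from riboclass.sequence_io import RiboswitchDataset, SequenceRecord
from riboclass.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_records():
    return [
        SequenceRecord("a1", "ACGTACGTAA", label="famA"),
        SequenceRecord("a2", "ACGTACGTTT", label="famA"),
        SequenceRecord("b1", "GGGGCCCCGG", label="famB"),
    ]


@pytest.fixture
def tiny_dataset(tiny_records):
    return RiboswitchDataset(tiny_records)


@pytest.fixture(scope="session")
def small_generated():
    """A 4-family dataset small enough for fast model fits."""
    spec = SyntheticSpec(
        n_classes=4,
        n_per_class=60,
        length_range=(50, 70),
        motif_length=12,
        motif_mutation_rate=0.02,
        seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
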