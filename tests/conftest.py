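import numpy as np
import pytest

from ovatome import ReadRecord, SimulationConfig


@pytest.fixture
def cfg():
    return SimulationConfig(seed=1)


def make_read(read_id: str, sequence: str, q: int = 36) -> ReadRecord:
    return ReadRecord(read_id, sequence, [q] * len(sequence))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
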