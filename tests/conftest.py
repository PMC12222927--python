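import numpy as np
import pytest

from lncspect import SequenceRecord, SyntheticConfig, generate

BASES = "ACGT"


def random_record(rng: np.random.Generator, length: int, rid: str = "r") -> SequenceRecord:
    seq = "".join(rng.choice(list(BASES), size=length))
    return SequenceRecord(rid, seq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """100 coding-like + 100 noncoding-like synthetic transcripts."""
    return generate(SyntheticConfig(n_coding=100, n_noncoding=100, seed=11))


@pytest.fixture(scope="session")
def random_records():
    """200 uniform-random sequences, lengths 50-500, for oracle checks."""
    r = np.random.default_rng(777)
    return [random_record(r, int(r.integers(50, 501)), f"rand_{i}") for i in range(200)]
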