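import numpy as np
import pytest

from agrpipe.core_io import SequenceRecord, StrandedInterval
from agrpipe.synthetic_data import default_ctcf_library


@pytest.fixture(scope="session")
def library():
    return default_ctcf_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def random_genome(rng):
    return SequenceRecord("chrT", random_sequence(rng, 5000))


def make_interval(start, end, strand=".", chrom="chr1", name=".", score=0.0):
    return StrandedInterval(chrom, start, end, name, score, strand)
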