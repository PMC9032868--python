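import numpy as np
import pytest

from isoscan import synthetic
from isoscan.flnc import PrimerPair
from isoscan.io_formats import SeqRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def primers():
    return PrimerPair(
        five=synthetic.DEFAULT_PRIMER_5, three=synthetic.DEFAULT_PRIMER_3
    )


@pytest.fixture
def random_record(rng):
    def _make(length: int = 500, rid: str = "rec"):
        return SeqRecord(id=rid, sequence=synthetic.random_dna(rng, length))

    return _make
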