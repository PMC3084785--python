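import numpy as np
import pytest

from nifhamp.qc import Profile, ProteinSeq
from nifhamp.simulate import CONSENSUS, VARIABLE_POSITIONS


@pytest.fixture(scope="session")
def profile() -> Profile:
    return Profile.from_consensus(CONSENSUS, VARIABLE_POSITIONS)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_pseq(seq_id: str, aa: str, counts: dict[str, int]) -> ProteinSeq:
    return ProteinSeq(seq_id, aa, counts)
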