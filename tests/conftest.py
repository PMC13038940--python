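import numpy as np
import pytest

from stackpvp.pssm_io import PssmProfile
from stackpvp.sequence_io import STANDARD_AA, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_profile(rng, length=None, low=-10, high=10) -> PssmProfile:
    """A random integer log-odds profile with a random residue string."""
    if length is None:
        length = int(rng.integers(2, 13))
    scores = rng.integers(low, high + 1, size=(length, 20)).astype(float)
    residues = "".join(rng.choice(list(STANDARD_AA), size=length))
    return PssmProfile(residues=residues, scores=scores)


def random_record(rng, length=None, prefix="r") -> ProteinRecord:
    if length is None:
        length = int(rng.integers(2, 300))
    seq = "".join(rng.choice(list(STANDARD_AA), size=length))
    return ProteinRecord(id=f"{prefix}{rng.integers(1e9)}", sequence=seq)


@pytest.fixture
def zero_profile():
    return PssmProfile(residues="ACDEF", scores=np.zeros((5, 20)))
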