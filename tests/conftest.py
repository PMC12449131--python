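import numpy as np
import pytest

from actalign.core import BacktrackPolicy, ScoringScheme, Sequence

# the worked example pair used throughout: two short DNA sequences whose
# optimal local alignment under (match=2, mismatch=-1, gap=-2) scores 6
WORKED_P = "ATCGACTT"
WORKED_Q = "GATATCTG"


@pytest.fixture(scope="session")
def scheme():
    """Default linear scoring: match=2, mismatch=-1, gap penalty 2."""
    return ScoringScheme.linear(2, -1, -2)


@pytest.fixture(scope="session")
def affine_scheme():
    return ScoringScheme.affine(2, -1, 4, 1)


@pytest.fixture(scope="session")
def policy():
    return BacktrackPolicy()


@pytest.fixture(scope="session")
def worked_pair():
    return Sequence("p", WORKED_P), Sequence("q", WORKED_Q)


def random_pair(rng: np.random.Generator, max_len: int, min_len: int = 1):
    """One random DNA pair with independent uniform lengths."""
    letters = np.array(list("ACGT"))
    m = int(rng.integers(min_len, max_len + 1))
    n = int(rng.integers(min_len, max_len + 1))
    p = "".join(rng.choice(letters, m))
    q = "".join(rng.choice(letters, n))
    return Sequence(f"p{m}", p), Sequence(f"q{n}", q)
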