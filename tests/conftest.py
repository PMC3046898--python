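import hypothesis.strategies as st
import numpy as np
import pytest
from hypothesis import settings

from seqorder import BaseComposition

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture
def sirtuin3():
    """Base composition of the human Sirtuin-3 gene (AF083108)."""
    return BaseComposition(0.174, 0.279, 0.333, 0.214)


@pytest.fixture
def x_fastidiosa():
    """Genome composition of X. fastidiosa 9a5c (NC_002488), as printed at
    4 significant figures (sums to 0.9999 before renormalization)."""
    return BaseComposition(0.2254, 0.2494, 0.2773, 0.2478)


@pytest.fixture
def uniform():
    return BaseComposition.uniform()


def random_compositions(n: int, seed: int) -> np.ndarray:
    """(n, 4) array of frequency vectors drawn uniformly on the simplex."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(4), size=n)


@st.composite
def compositions(draw):
    """Hypothesis strategy for valid base compositions."""
    raw = draw(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=4,
            max_size=4,
        ).filter(lambda v: sum(v) > 0.05)
    )
    total = sum(raw)
    return BaseComposition(*(v / total for v in raw))


@st.composite
def dna(draw, min_size=0, max_size=500):
    return draw(st.text(alphabet="ACGT", min_size=min_size, max_size=max_size))
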