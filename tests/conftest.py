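import numpy as np
import pytest

from mobsir.dynamics import HealthStateVector
from mobsir.geometry import ContactSet, initialize_particles


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_ensemble():
    return initialize_particles(64, 200.0, seed=7)


def make_contacts(pairs, n) -> ContactSet:
    """ContactSet from a plain pair list (test helper)."""
    pairs = np.asarray(sorted(tuple(sorted(p)) for p in pairs), dtype=np.intp)
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
    return ContactSet(pairs=pairs, n=n)


def make_single_states(codes) -> HealthStateVector:
    return HealthStateVector(mode="single", a=np.asarray(codes, dtype=np.int8))


def make_dual_states(a_codes, b_codes) -> HealthStateVector:
    return HealthStateVector(
        mode="cooperative",
        a=np.asarray(a_codes, dtype=np.int8),
        b=np.asarray(b_codes, dtype=np.int8),
    )
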