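import numpy as np
import pytest

from songrec.stimuli import make_fit_grid
from songrec.synthetic import default_anurogryllus_spec, synth_preference_field


@pytest.fixture(scope="session")
def fit_grid_4k():
    """The standard 0.5 ms fitting lattice at the rebound model's 4 kHz."""
    return make_fit_grid(20.0, 0.5, sample_rate=4000.0)


@pytest.fixture(scope="session")
def fit_grid_10k():
    return make_fit_grid(20.0, 0.5, sample_rate=10_000.0)


@pytest.fixture(scope="session")
def anuro_field():
    """Synthetic Anurogryllus-like preference field on the 0.5 ms lattice."""
    return synth_preference_field(default_anurogryllus_spec())


def local_maxima(values: np.ndarray, floor_fraction: float = 0.0) -> np.ndarray:
    """Indices of interior local maxima above a fraction of the global max.

    Plateau-aware: a run of equal values counts as one maximum (its middle
    index) only if the values on both sides of the run are strictly lower;
    runs touching the array boundary are excluded.
    """
    v = np.asarray(values, dtype=float)
    floor = floor_fraction * v.max()
    out = []
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[j + 1] == v[i]:
            j += 1
        interior = i > 0 and j < v.size - 1
        if interior and v[i - 1] < v[i] and v[j + 1] < v[i] and v[i] > floor:
            out.append((i + j) // 2)
        i = j + 1
    return np.array(out, dtype=int)
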