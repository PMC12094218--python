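import numpy as np
import pytest

from cosinorpower import SamplingDesign, make_evenly_spaced, make_uniform_grid


@pytest.fixture
def quarter_day():
    """Evenly spaced design {0, 6, 12, 18}, period 24 h."""
    return make_evenly_spaced(n_per_cycle=4, period=24.0)


@pytest.fixture
def hourly():
    """Evenly spaced design {0, 1, ..., 23}, period 24 h."""
    return make_evenly_spaced(n_per_cycle=24, period=24.0)


@pytest.fixture
def clustered():
    """24 points squeezed uniformly into [ZT 5, ZT 7]: non-centered, ill-conditioned."""
    return make_uniform_grid(5.0, 7.0, 24, period=24.0)


def random_design(rng: np.random.Generator, n: int | None = None, period: float = 24.0) -> SamplingDesign:
    """A design with i.i.d. uniform times over one period (non-centered w.p. 1)."""
    if n is None:
        n = int(rng.integers(6, 40))
    return SamplingDesign(rng.uniform(0.0, period, size=n), period)
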