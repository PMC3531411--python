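import numpy as np
import pytest

from micropop import DropletSpec


@pytest.fixture
def toy_spec() -> DropletSpec:
    """Two types, equal rates, costs (1, 2), budget 3.

    Exact endpoint law (exhaustive 5-path enumeration):
    P(d1=0)=1/3, P(d1=1)=1/3, P(d1=2)=1/12, P(d1=3)=1/4;
    hence P(N_f=4)=2/3, P(N_f=5)=1/3, E[N_f]=13/3, Var[N_f]=2/9.
    """
    return DropletSpec.from_arrays(counts=(1, 1), rates=(1.0, 1.0), yields=(1.0, 0.5), budget=3.0)


@pytest.fixture
def uniform_spec():
    """Factory: single-cell-per-type inoculum, equal rates/yields, D divisions."""

    def make(D: int) -> DropletSpec:
        return DropletSpec.from_arrays(counts=(1, 1), rates=(1.0, 1.0), yields=(1.0, 1.0), budget=float(D))

    return make


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20260101))
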