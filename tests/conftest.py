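import numpy as np
import pytest

from swarmconvect import sideview as sv


@pytest.fixture(scope="session")
def small_params():
    """Coarse but physically meaningful side-view grid for unit tests."""
    return sv.SideViewParams(Nx=128, Nz=32)


@pytest.fixture(scope="session")
def short_run(small_params):
    """One shared rich-fuel run (c0=1.2) used by several conservation tests."""
    params = sv.SideViewParams(Nx=128, Nz=32, c0=1.2)
    drop = sv.DropSpec()
    return sv.run_side(params, drop, t_end=0.8, output_every=0.1, log_every=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
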