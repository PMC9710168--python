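import numpy as np
import pytest

from cellphantom import (
    PSFConfig,
    RenderIntensities,
    SimConfig,
    airy_psf,
    render_opl,
    run_simulation,
)


@pytest.fixture(scope="session")
def short_sim():
    """A 120-step default (adder) run shared across read-only tests."""
    return run_simulation(SimConfig(seed=1, n_timepoints=120))


@pytest.fixture(scope="session")
def packed_frame(short_sim):
    """A frame with a filled trench (several touching cells)."""
    return short_sim.frames[-1]


@pytest.fixture(scope="session")
def fluorescence_scene(packed_frame):
    """Noise-free fluorescence-style scene: cells on a dark background."""
    return render_opl(
        packed_frame, RenderIntensities(cell=1.0, trench=0.0, media=0.0)
    )


@pytest.fixture(scope="session")
def airy_kernel():
    return airy_psf(PSFConfig(mode="fluorescence"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
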