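import numpy as np
import pytest

from dmirelax.phantom import (
    CompartmentParams,
    RelaxationSchedule,
    TissuePhantom,
    make_two_compartment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240717)


@pytest.fixture
def small_phantom():
    """32-cube two-compartment phantom with the default relaxation times."""
    return make_two_compartment((32, 32, 32))


@pytest.fixture
def uniform_phantom():
    """Two compartments with identical parameters: effectively a single
    homogeneous tissue (used for exact-proportionality checks)."""
    a = CompartmentParams("sGM", t1_ms=350.0, t2_ms=35.0)
    b = CompartmentParams("sWM", t1_ms=350.0, t2_ms=35.0)
    return make_two_compartment((32, 32, 32), params=(a, b))


@pytest.fixture
def single_voxel_phantom():
    """1-voxel phantom helper: one compartment filling the voxel."""

    def _make(t1=350.0, t2=35.0, amplitude=1.0):
        comp = CompartmentParams("tissue", t1_ms=t1, t2_ms=t2,
                                 amplitude=amplitude)
        filler = CompartmentParams("rest", t1_ms=1.0, t2_ms=1.0, amplitude=0.0)
        masks = (np.ones((1, 1, 1), bool), np.zeros((1, 1, 1), bool))
        # explicit masks: compartment "tissue" is the shell slot
        return TissuePhantom(
            (1, 1, 1), (1.0, 1.0, 1.0),
            {"tissue": masks[0].astype(float), "rest": masks[1].astype(float)},
            [comp, filler],
        )

    return _make


@pytest.fixture
def ir_schedule():
    return RelaxationSchedule("IR", (5.0, 230.0, 455.0, 680.0, 900.0))


@pytest.fixture
def se_schedule():
    return RelaxationSchedule("SE", (6.0, 15.0, 24.0, 33.0, 42.0, 51.0, 60.0))
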