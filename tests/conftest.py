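import numpy as np
import pytest

from nirsbench import (
    Geometry,
    IRFModel,
    InstrumentModel,
    OpticalProperties,
    make_irf,
)


@pytest.fixture(scope="session")
def geometry():
    return Geometry()  # reflectance at 30 mm


@pytest.fixture(scope="session")
def b2_props():
    return OpticalProperties(mua=0.05, musp=10.0)


@pytest.fixture(scope="session")
def b3_props():
    return OpticalProperties(mua=0.1, musp=10.0)


@pytest.fixture(scope="session")
def ideal_instrument():
    """Defect-free instrument: narrow IRF, no dark, DNL, drift or jitter."""
    return InstrumentModel.ideal()


@pytest.fixture(scope="session")
def delta_instrument():
    """Instrument whose IRF occupies a single channel (exact delta kernel)."""
    return InstrumentModel(irf=IRFModel(fwhm_ps=1.0), channel_width_ps=10.0)


@pytest.fixture(scope="session")
def ideal_irf(ideal_instrument):
    return make_irf(ideal_instrument.irf, ideal_instrument, total_counts=1e6)


@pytest.fixture(scope="session")
def time_grid():
    return np.linspace(10.0, 5000.0, 250)
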