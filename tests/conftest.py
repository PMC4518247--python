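"""Shared fixtures: the study beam, detector response and geometries."""

import numpy as np
import pytest

import betaxct as bx


@pytest.fixture(scope="session")
def chitin():
    return bx.chitin()


@pytest.fixture(scope="session")
def aluminium():
    return bx.aluminium()


@pytest.fixture(scope="session")
def beam_spectrum():
    """Synchrotron-like beam (E_c = 4.9 keV) behind the 20 μm Al foil."""
    grid = np.linspace(1.0, 20.0, 24)
    spec = bx.filter_transmission(bx.aluminium(), 20.0,
                                  bx.synchrotron_spectrum(4.9, grid))
    return spec.normalized()


@pytest.fixture(scope="session")
def detector_response():
    """Deep-depletion CCD behind its 10 μm Al window, energy-weighted."""
    return bx.ccd_response(depletion_um=50.0, foil_um=10.0)


@pytest.fixture(scope="session")
def tomo_arm():
    """The full tomography arm: l = 0.73 m, d = 1.99 m (M = 3.7)."""
    return bx.make_geometry(0.73, 1.99)


@pytest.fixture(scope="session")
def wire_arm():
    """The wire-diagnostic arm: wire 0.26 m behind the source, detector at
    3.26 m."""
    return bx.make_geometry(0.26, 3.00)


@pytest.fixture(scope="session")
def scaled_arm():
    """Short imaging arm of the scaled tomography study (M = 1.36)."""
    return bx.make_geometry(0.73, 0.26)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
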