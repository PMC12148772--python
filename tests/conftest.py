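import numpy as np
import pytest

from kvdose.materials import load_material
from kvdose.spectrum import calibrate_filtration, tube_spectrum
from kvdose.synthetic_data import toy_material

#: the three machine techniques: kvp -> stated HVL (mm Al)
TECHNIQUES = {50: 0.45, 70: 1.10, 100: 2.10}


@pytest.fixture(scope="session")
def water():
    return load_material("water")


@pytest.fixture(scope="session")
def bone():
    return load_material("bone")


@pytest.fixture(scope="session")
def air():
    return load_material("air")


@pytest.fixture(scope="session")
def aluminum():
    return load_material("aluminum")


@pytest.fixture(scope="session")
def calibrated_beams():
    """kvp -> (added_al_mm, calibrated BeamSpectrum) for the three
    techniques, each matched to its stated half-value layer."""
    out = {}
    for kvp, target in TECHNIQUES.items():
        al_mm = calibrate_filtration(kvp, target)
        out[kvp] = (al_mm, tube_spectrum(kvp, 0.8, al_mm))
    return out


@pytest.fixture()
def flat_toy():
    """Flat mu/rho = 1 cm2/g toy material (mu = 1/cm at unit density)."""
    pts = [(5.0, 1.0), (150.0, 1.0)]
    return toy_material(pts, [(5.0, 0.5), (150.0, 0.5)],
                        partial_split=(1.0, 0.0, 0.0), density=1.0)


@pytest.fixture()
def mono_spectrum():
    """Single-bin (monoenergetic) 30 keV beam spectrum."""
    from kvdose.spectrum import BeamSpectrum
    return BeamSpectrum(kvp=30.0, bin_edges=np.array([29.4, 29.6]),
                        fluence=np.array([1.0]))
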