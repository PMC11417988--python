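import numpy as np
import pytest

from gtafit.irf_ca import IRFModel, Oscillation
from gtafit.kinetics import Channel, KineticScheme
from gtafit.synthetic_data import lycopene_preset, make_time_axis


@pytest.fixture
def two_state_scheme() -> KineticScheme:
    """A -> B cascade with a ground-state loss from A (rates in ns^-1)."""
    return KineticScheme(
        ["A", "B"],
        [
            Channel("A", "B", 600.0),
            Channel("A", "GS", 400.0),
            Channel("B", "GS", 250.0),
        ],
    )


@pytest.fixture
def ta_irf() -> IRFModel:
    return IRFModel(mu0=0.0, sigma=0.097 / 2.3548)


@pytest.fixture
def fsrs_irf() -> IRFModel:
    return IRFModel(
        mu0=0.0,
        sigma=0.180 / 2.3548,
        dispersion=(0.03, -0.004),
        center=1300.0,
    )


@pytest.fixture
def backward_osc() -> Oscillation:
    return Oscillation(omega=1511.0, gamma=2.0, direction="backward")


@pytest.fixture
def delays() -> np.ndarray:
    return make_time_axis()


@pytest.fixture
def small_preset():
    """Lycopene preset at reduced pixel counts for fast fits."""
    return lycopene_preset(n_pixels_fsrs=40, n_pixels_ta=24)
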