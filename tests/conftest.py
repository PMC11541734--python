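import numpy as np
import pytest

from optigpp import photo_core as pc
from optigpp import synthgen as sg


@pytest.fixture(scope="session")
def params() -> pc.PhotoParams:
    return pc.PhotoParams()


@pytest.fixture(scope="session")
def std_forcing() -> pc.MonthlyForcing:
    """Standard conditions: 25 degC, 1 kPa VPD, 400 ppm CO2, sea level."""
    return pc.MonthlyForcing(tc=25.0, vpd=1000.0, co2=400.0, patm=101325.0,
                             ppfd=1000.0)


@pytest.fixture(scope="session")
def dataset(params):
    """Default-condition synthetic three-site dataset (fixed seed)."""
    return sg.generate_dataset(seed=1234, params=params)


@pytest.fixture(scope="session")
def neutral(params):
    """Zero-perturbation site template and its calibrated lookup params."""
    return sg.neutral_template(params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def random_forcing(rng: np.random.Generator) -> pc.MonthlyForcing:
    """A random but physically plausible tropical forcing record."""
    return pc.MonthlyForcing(
        tc=float(rng.uniform(15.0, 35.0)),
        vpd=float(rng.uniform(10.0, 3000.0)),
        co2=float(rng.uniform(350.0, 450.0)),
        patm=float(rng.uniform(85000.0, 101325.0)),
        ppfd=float(rng.uniform(500.0, 1500.0)),
    )
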