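import numpy as np
import pytest

import tetrasec as ts


@pytest.fixture(scope="session")
def instrument() -> ts.InstrumentModel:
    return ts.InstrumentModel()


@pytest.fixture(scope="session")
def noiseless_instrument(instrument) -> ts.InstrumentModel:
    return instrument.noiseless()


@pytest.fixture(scope="session")
def bsa_standard() -> ts.CalibrationStandard:
    return ts.fixture_standard()


@pytest.fixture(scope="session")
def constants(bsa_standard) -> ts.CalibrationConstants:
    """Constants calibrated from a noiseless simulated BSA run."""
    run = ts.simulate_fixture("bsa_standard", seed=0, noiseless=True)
    return ts.calibrate_from_standard(run, bsa_standard)


@pytest.fixture(scope="session")
def true_constants() -> ts.CalibrationConstants:
    """The constants the default instrument model simulates with."""
    return ts.simulate.DEFAULT_CONSTANTS


def single_species(mw=100.0, dndc=1.0, iv=1.0, dadc=1.0, vr=9.0, sigma=0.15,
                   name="sp") -> ts.SpeciesSpec:
    return ts.SpeciesSpec(name=name, mw=mw, dndc=dndc, iv=iv, dadc=dadc,
                          mass_fraction=1.0, vr=vr, sigma=sigma)


@pytest.fixture(scope="session")
def unit_instrument() -> ts.InstrumentModel:
    """All detector constants 1, no noise: areas equal the physical products."""
    return ts.InstrumentModel(
        constants=ts.CalibrationConstants(k_ri=1.0, k_ls=1.0, k_uv=1.0, k_visc=1.0),
        noise_sd=0.0, baseline_drift=0.0,
    )
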