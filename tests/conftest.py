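import numpy as np
import pytest

import photodose as pv
from photodose.plate import PlateFormat


@pytest.fixture(scope="session")
def fixture_set() -> pv.FixtureSet:
    return pv.generate_fixtures(seed=1)


@pytest.fixture()
def pwm_cfg() -> pv.PwmConfig:
    return pv.PwmConfig()


@pytest.fixture()
def linear_calib_400() -> pv.IrradianceCalibration:
    return pv.IrradianceCalibration.linear(400.0)


@pytest.fixture()
def canonical_layout() -> pv.PlateLayout:
    return pv.canonical_96well_layout()


@pytest.fixture()
def centred_3x3():
    """A 3x3 well block whose centre well sits at the array origin."""
    fmt = PlateFormat(a1_offset_mm=(-9.0, -9.0))
    wells = [f"{r}{c}" for r in "ABC" for c in (1, 2, 3)]
    return fmt, wells


def gaussian_spectrum(peak_nm: float, fwhm_nm: float,
                      grid=None) -> pv.Spectrum:
    grid = np.arange(600.0, 780.0, 0.25) if grid is None else grid
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return pv.Spectrum(grid, np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2))
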