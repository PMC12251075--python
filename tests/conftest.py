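import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import flowspec as fs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def geometry():
    return fs.FlowCellGeometry()


@pytest.fixture(scope="session")
def dyes():
    """(TZ, EG) default dye pair."""
    return fs.default_dyes()


@pytest.fixture(scope="session")
def noiseless_detector():
    return fs.DetectorConfig(relative_noise_sd=0.0)


@pytest.fixture(scope="session")
def uncrossed_dyes():
    """A (TZ, EG)-like pair with no secondary bands: zero cross-absorption at
    the opposite measurement wavelength (widths keep the tails negligible)."""
    tz = fs.DyeDefinition(
        "TZ",
        fs.make_dye_spectrum(424.0, 15.0, 0.0012, dye_name="TZ"),
        100.0,
    )
    eg = fs.DyeDefinition(
        "EG",
        fs.make_dye_spectrum(631.0, 15.0, 0.0048, dye_name="EG"),
        25.0,
    )
    return tz, eg
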