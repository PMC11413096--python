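import logging

import numpy as np
import pytest

from exoantenna.spectra import StellarModel, planet_flux

# large-pool warnings are expected all over the sweeps; keep test output clean
logging.getLogger("exoantenna.antenna").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sun() -> StellarModel:
    """5800 K, 0.936 R_sun — the Sun-like reference star."""
    return StellarModel.from_solar(5800.0, 0.936)


@pytest.fixture(scope="session")
def sun_flux(sun):
    """Blackbody flux at the mid habitable distance of the reference star."""
    return planet_flux(sun)


@pytest.fixture(scope="session")
def coarse_sizes():
    """Small log-spaced pigment-count grid for fast sweeps."""
    return np.unique(np.round(np.logspace(0, 3, 8)).astype(int))
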