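import numpy as np
import pandas as pd
import pytest

from soycanopy import PhotosynthesisParams, generate_archive
from soycanopy.canopy import CanopyArchitecture
from soycanopy.growth import PartitionSchedule
from soycanopy.weather import WEATHER_COLUMNS, WeatherArchive


@pytest.fixture(scope="session")
def params():
    return PhotosynthesisParams.from_yaml()


@pytest.fixture(scope="session")
def arch():
    return CanopyArchitecture()


@pytest.fixture(scope="session")
def schedule():
    return PartitionSchedule.from_config()


@pytest.fixture(scope="session")
def archive2():
    """Two synthetic weather years; the default small-experiment archive."""
    return generate_archive(2, seed=11)


@pytest.fixture(scope="session")
def archive10():
    """Ten synthetic years emulating the decade-scale station archive."""
    return generate_archive(10, seed=42)


def make_tiny_archive(n_years=3, n_doys=20, seed=3):
    """Small hand-buildable archive (n_years x n_doys x 24 h) for fast
    bootstrap/validation tests; values carry a year signature so block
    provenance is checkable by equality."""
    rng = np.random.default_rng(seed)
    rows = []
    for iy in range(n_years):
        year = 2001 + iy
        for doy in range(1, n_doys + 1):
            base_t = 15.0 + iy + 0.1 * doy
            for hour in range(24):
                rows.append({
                    "year": year, "doy": doy, "hour": hour,
                    "q_umol_m2_s": max(0.0, 1000.0 * np.sin(np.pi * (hour - 6) / 12.0)) * (1 + 0.01 * iy),
                    "t_c": base_t + 5.0 * np.sin(np.pi * (hour - 9) / 12.0),
                    "rh_frac": min(1.0, 0.6 + 0.01 * iy + 0.001 * doy),
                    "ws_m_s": 2.0 + 0.1 * iy,
                    "precip_mm": float(rng.random() < 0.05),
                })
    return WeatherArchive(pd.DataFrame(rows, columns=WEATHER_COLUMNS),
                          provenance="tiny-test")


@pytest.fixture(scope="session")
def tiny_archive():
    return make_tiny_archive()
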