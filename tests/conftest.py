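import numpy as np
import pandas as pd
import pytest

from tagtrack import GridSpec, ScenarioConfig, generate_scenario
from tagtrack.grid import ReferenceFields


@pytest.fixture(scope="session")
def scenario():
    """A small deterministic synthetic campaign shared across tests."""
    return generate_scenario(ScenarioConfig(seed=1, duration_days=6, n_fish=6))


@pytest.fixture()
def tiny_grid():
    """3x3 grid with a land cell in the middle."""
    sea = np.ones((3, 3), dtype=bool)
    sea[1, 1] = False
    return GridSpec(lon=np.array([0.0, 0.02, 0.04]),
                    lat=np.array([50.0, 50.02, 50.04]),
                    sea_mask=sea)


@pytest.fixture()
def tiny_fields(tiny_grid):
    """Hourly fields on the tiny grid: uniform 100 m depth except one
    10 m shoal, flat ssh, temperature decreasing eastward at depth."""
    T = 6
    times = pd.date_range("2022-06-01", periods=T, freq="h")
    bathy = np.full((3, 3), 100.0)
    bathy[0, 0] = 10.0
    bathy[1, 1] = 0.0
    ssh = np.zeros((T, 3, 3))
    levels = np.array([0.0, 50.0])
    lon_grad = np.array([14.0, 13.0, 12.0])
    temp = np.zeros((T, 2, 3, 3))
    temp[:, 0] = lon_grad[None, None, :]
    temp[:, 1] = lon_grad[None, None, :] - 1.0
    temp[:, :, 0, 0] = np.nan  # shoal: no 50 m level
    temp[:, 1, 0, 0] = np.nan
    temp[:, 0, 0, 0] = 14.0
    temp[:, :, 1, 1] = np.nan  # land
    return ReferenceFields.from_arrays(tiny_grid, times.values, levels,
                                       bathy, ssh, temp)


@pytest.fixture()
def qc_tables():
    """Three receivers, two fish, hand-built for QC rule tests."""
    receivers = pd.DataFrame({
        "receiver_id": ["R1", "R2", "R3"],
        "station": ["S1", "S2", "S3"],
        "lon": [-4.9, -4.9, -4.78],  # S3 ~ 9 km east of S1
        "lat": [48.0, 48.09, 48.0],
        "start": pd.to_datetime(["2022-06-01"] * 3),
        "end": pd.to_datetime(["2022-09-01"] * 3),
        "detection_range_m": [400.0] * 3,
        "protocol": ["OPi"] * 3,
    })
    fish = pd.DataFrame({
        "acoustic_tag_id": ["F1", "F2"],
        "archival_tag_id": ["D1", ""],
        "total_length_mm": [500, 420],
        "release_time": pd.to_datetime(["2022-06-10 12:00:00"] * 2),
        "release_lon": [-4.9, -4.9],
        "release_lat": [48.0, 48.0],
        "recapture_time": [pd.NaT, pd.NaT],
        "recapture_lon": [np.nan, np.nan],
        "recapture_lat": [np.nan, np.nan],
        "maturity": ["mature", "immature"],
    })
    return receivers, fish


def make_detections(rows):
    """rows: (tag_id, iso_time, receiver_id, station, lon, lat, snr)"""
    df = pd.DataFrame(rows, columns=["tag_id", "timestamp", "receiver_id",
                                     "station", "lon", "lat", "snr"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values(["tag_id", "timestamp"]).reset_index(drop=True)
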