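"""Regular lat/lon grid, environmental reference fields, and great-circle
distance.

The geolocation model discretises the sea into a regular WGS84 lat/lon grid
(``GridSpec``) and compares tag records against gridded environmental fields
(``ReferenceFields``): bathymetry, hourly sea-surface height, and hourly
temperature on vertical levels.  Depth is positive down everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .config import EARTH_RADIUS_KM

__all__ = ["GridSpec", "ReferenceFields", "haversine_km"]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance (km) between points, vectorised.

    Uses the haversine formula on a sphere of mean radius 6371.0 km.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _check_regular(axis: np.ndarray, name: str) -> float:
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError(f"{name} axis must be 1-D with at least 2 points")
    steps = np.diff(axis)
    if not np.all(steps > 0):
        raise ValueError(f"{name} axis must be strictly increasing")
    step = float(steps[0])
    if not np.allclose(steps, step, rtol=0.0, atol=1e-9):
        raise ValueError(f"{name} axis step not uniform to 1e-9")
    return step


@dataclass
class GridSpec:
    """Regular lat/lon grid with a boolean sea mask.

    ``sea_mask`` has shape ``(n_lat, n_lon)`` with True on water cells.
    """

    lon: np.ndarray
    lat: np.ndarray
    sea_mask: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.sea_mask = np.asarray(self.sea_mask, dtype=bool)
        self.lon_step = _check_regular(self.lon, "lon")
        self.lat_step = _check_regular(self.lat, "lat")
        if self.sea_mask.shape != (self.lat.size, self.lon.size):
            raise ValueError(
                f"sea_mask shape {self.sea_mask.shape} != (n_lat, n_lon) "
                f"({self.lat.size}, {self.lon.size})")
        if not self.sea_mask.any():
            raise ValueError("grid has no sea cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sea_mask.shape

    @property
    def n_cells(self) -> int:
        return self.sea_mask.size

    def cell_size_km(self) -> tuple[float, float]:
        """Mean (east-west, north-south) cell size in km."""
        lat_mid = float(self.lat.mean())
        dx = haversine_km(0.0, lat_mid, self.lon_step, lat_mid)
        dy = haversine_km(0.0, lat_mid, 0.0, lat_mid + self.lat_step)
        return float(dx), float(dy)

    def mean_cell_km(self) -> float:
        dx, dy = self.cell_size_km()
        return 0.5 * (dx + dy)

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(iy, ix) of the cell whose centre is nearest to (lon, lat).

        Raises if the point falls outside the grid bounding box (half a
        cell beyond the outermost centres).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix = np.rint((lon - self.lon[0]) / self.lon_step).astype(int)
        iy = np.rint((lat - self.lat[0]) / self.lat_step).astype(int)
        if np.any(ix < 0) or np.any(ix >= self.lon.size) or \
           np.any(iy < 0) or np.any(iy >= self.lat.size):
            raise ValueError("point outside grid bounding box")
        return iy, ix

    def cell_center(self, iy, ix) -> tuple[np.ndarray, np.ndarray]:
        return self.lon[np.asarray(ix)], self.lat[np.asarray(iy)]

    def is_sea(self, lon, lat) -> np.ndarray:
        iy, ix = self.cell_index(lon, lat)
        return self.sea_mask[iy, ix]


@dataclass
class ReferenceFields:
    """Gridded environmental fields the geolocation model compares against.

    Wraps an :class:`xarray.Dataset` with variables

    - ``bathymetry (lat, lon)`` — metres, positive down, NaN/0 on land;
    - ``ssh (time, lat, lon)`` — sea-surface height anomaly, metres;
    - ``temperature (time, level, lat, lon)`` — °C at vertical levels;

    and a ``level`` coordinate giving level depths in metres (positive
    down, increasing).  The time axis is hourly and contiguous.
    """

    ds: xr.Dataset
    grid: GridSpec = field(repr=False)

    @classmethod
    def from_arrays(cls, grid: GridSpec, times: np.ndarray,
                    level_depths: np.ndarray, bathymetry: np.ndarray,
                    ssh: np.ndarray, temperature: np.ndarray,
                    ) -> "ReferenceFields":
        ds = xr.Dataset(
            {
                "bathymetry": (("lat", "lon"), np.asarray(bathymetry)),
                "ssh": (("time", "lat", "lon"), np.asarray(ssh)),
                "temperature": (("time", "level", "lat", "lon"),
                                np.asarray(temperature)),
                "sea_mask": (("lat", "lon"), grid.sea_mask),
            },
            coords={
                "time": pd.DatetimeIndex(times),
                "level": np.asarray(level_depths, dtype=float),
                "lat": grid.lat,
                "lon": grid.lon,
            },
        )
        obj = cls(ds=ds, grid=grid)
        obj.validate()
        return obj

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.ds["time"].values)

    @property
    def level_depths(self) -> np.ndarray:
        return self.ds["level"].values

    def validate(self) -> None:
        t = self.times
        if len(t) >= 2:
            dt = np.diff(t.values)
            if not np.all(dt == np.timedelta64(1, "h")):
                raise ValueError("reference field time axis must be hourly and contiguous")
        lv = self.level_depths
        if lv.ndim != 1 or np.any(np.diff(lv) <= 0) or np.any(lv < 0):
            raise ValueError("level depths must be non-negative and increasing")
        bathy = self.ds["bathymetry"].values
        sea = self.grid.sea_mask
        if np.any(~np.isfinite(bathy[sea])) or np.any(bathy[sea] < 0):
            raise ValueError("bathymetry must be finite and >= 0 on sea cells")
        temp = self.ds["temperature"].values
        # finite wherever the level is shallower than the local water column
        shallower = lv[None, :, None, None] <= bathy[None, None, :, :]
        bad = ~np.isfinite(temp) & shallower & sea[None, None, :, :]
        if bad.any():
            raise ValueError("temperature not finite on sea cells above the seabed")

    def water_depth(self, when) -> np.ndarray:
        """Instantaneous water-column depth (m): bathymetry + ssh(t)."""
        it = self.time_index(when)
        bathy = self.ds["bathymetry"].values
        return bathy + self.ds["ssh"].values[it]

    def time_index(self, when) -> int:
        t = self.times
        when = pd.Timestamp(when)
        idx = t.get_indexer([when])
        if idx[0] < 0:
            raise KeyError(f"hour {when} not covered by reference fields")
        return int(idx[0])

    def to_netcdf(self, path: str | Path) -> None:
        enc = {v: {"zlib": False} for v in self.ds.data_vars}
        self.ds.to_netcdf(path, encoding=enc)

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "ReferenceFields":
        ds = xr.load_dataset(path)
        grid = GridSpec(lon=ds["lon"].values, lat=ds["lat"].values,
                        sea_mask=ds["sea_mask"].values.astype(bool))
        obj = cls(ds=ds, grid=grid)
        obj.validate()
        return obj
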