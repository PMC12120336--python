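"""Readers and writers for tabular telemetry inputs.

All tables are plain CSV with ISO-8601 UTC timestamps; coordinates are
WGS84 decimal degrees (west negative).  Readers collect row-level problems
into a :class:`ParseReport` instead of failing wholesale, but a missing
column is a hard error.  Round-trips are lossless at the stated precision
(timestamps to 1 s, coordinates to 1e-6 deg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import LMAT50_MM

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["tag_id", "timestamp", "receiver_id", "station", "lon", "lat", "snr"]
RECEIVER_COLUMNS = ["receiver_id", "station", "lon", "lat", "start", "end",
                    "detection_range_m", "protocol"]
FISH_COLUMNS = ["acoustic_tag_id", "archival_tag_id", "total_length_mm",
                "release_time", "release_lon", "release_lat",
                "recapture_time", "recapture_lon", "recapture_lat"]
SENSOR_COLUMNS = ["timestamp", "depth_m", "temperature_c"]

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


@dataclass
class RowError:
    line: int          # 1-based line number in the file (header = line 1)
    reason: str


@dataclass
class ParseReport:
    n_rows: int = 0
    rejects: list[RowError] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


@dataclass
class SensorSeries:
    """A single tag's archival (depth/temperature) record.

    ``data`` columns: timestamp (UTC), depth_m (positive down),
    temperature_c.  Nominal cadence 90 s; gaps allowed.
    """

    tag_id: str
    data: pd.DataFrame

    @property
    def median_dt_s(self) -> float:
        if len(self.data) < 2:
            return float("nan")
        return float(self.data["timestamp"].diff().dt.total_seconds().median())


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _parse_times(raw: pd.Series) -> pd.Series:
    return pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601"
                          ).dt.tz_localize(None)


def read_detections(path: str | Path,
                    bbox: tuple[float, float, float, float] | None = None,
                    ) -> tuple[pd.DataFrame, ParseReport]:
    """Read an ETN-style detection table.

    Rows with unparseable timestamps or coordinates (or coordinates outside
    ``bbox`` = (lon_min, lon_max, lat_min, lat_max) when given) are dropped
    and reported with their file line numbers.  Output is sorted by
    (tag_id, timestamp).
    """
    df = pd.read_csv(path, dtype={"tag_id": str, "receiver_id": str, "station": str})
    _require_columns(df, [c for c in DETECTION_COLUMNS if c != "snr"], path)
    if "snr" not in df.columns:
        df["snr"] = np.nan
    report = ParseReport(n_rows=len(df))
    lines = df.index + 2  # header is line 1

    ts = _parse_times(df["timestamp"])
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    snr = pd.to_numeric(df["snr"], errors="coerce")

    bad = ts.isna()
    for ln, raw in zip(lines[bad], df.loc[bad, "timestamp"]):
        report.rejects.append(RowError(int(ln), f"unparseable timestamp {raw!r}"))
    bad_coord = (~bad) & (lon.isna() | lat.isna())
    if bbox is not None:
        lon_min, lon_max, lat_min, lat_max = bbox
        bad_coord |= (~bad) & ~((lon >= lon_min) & (lon <= lon_max)
                                & (lat >= lat_min) & (lat <= lat_max))
    for ln in lines[bad_coord]:
        report.rejects.append(RowError(int(ln), "invalid or out-of-bounds coordinates"))

    keep = ~(bad | bad_coord)
    out = pd.DataFrame({
        "tag_id": df.loc[keep, "tag_id"],
        "timestamp": ts[keep],
        "receiver_id": df.loc[keep, "receiver_id"],
        "station": df.loc[keep, "station"],
        "lon": lon[keep], "lat": lat[keep], "snr": snr[keep],
    })
    out = out.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    if report.n_rejected:
        log.warning("%s: rejected %d of %d rows", path, report.n_rejected, report.n_rows)
    return out, report


def write_detections(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(_TIME_FMT)
    out["lon"] = out["lon"].map(lambda v: f"{v:.6f}")
    out["lat"] = out["lat"].map(lambda v: f"{v:.6f}")
    out["snr"] = out["snr"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    out[DETECTION_COLUMNS + [c for c in out.columns if c not in DETECTION_COLUMNS]
        ].to_csv(path, index=False)


def read_receivers(path: str | Path) -> pd.DataFrame:
    """Read receiver deployment metadata; start < end and range > 0 enforced."""
    df = pd.read_csv(path, dtype={"receiver_id": str, "station": str, "protocol": str})
    _require_columns(df, RECEIVER_COLUMNS, path)
    df["start"] = _parse_times(df["start"])
    df["end"] = _parse_times(df["end"])
    df["detection_range_m"] = pd.to_numeric(df["detection_range_m"])
    bad = (df["start"] >= df["end"]) | (df["detection_range_m"] <= 0) \
        | df["start"].isna() | df["end"].isna()
    if bad.any():
        raise ValueError(f"{path}: invalid deployment rows at lines "
                         f"{[int(i) + 2 for i in df.index[bad]]}")
    return df.reset_index(drop=True)


def write_receivers(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for c in ("start", "end"):
        out[c] = pd.DatetimeIndex(out[c]).strftime(_TIME_FMT)
    for c in ("lon", "lat"):
        out[c] = out[c].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def read_fish(path: str | Path) -> pd.DataFrame:
    """Read fish metadata; derives a ``maturity`` column from total length
    (mature iff total_length_mm >= Lmat50)."""
    df = pd.read_csv(path, dtype={"acoustic_tag_id": str, "archival_tag_id": str})
    _require_columns(df, FISH_COLUMNS, path)
    for c in ("release_time", "recapture_time"):
        df[c] = _parse_times(df[c])
    has_recap = df["recapture_time"].notna()
    bad = has_recap & (df["recapture_time"] <= df["release_time"])
    if bad.any():
        raise ValueError(f"{path}: recapture precedes release at lines "
                         f"{[int(i) + 2 for i in df.index[bad]]}")
    df["maturity"] = np.where(df["total_length_mm"] >= LMAT50_MM, "mature", "immature")
    return df.reset_index(drop=True)


def write_fish(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for c in ("release_time", "recapture_time"):
        ts = pd.DatetimeIndex(out[c])
        out[c] = [("" if pd.isna(t) else t.strftime(_TIME_FMT)) for t in ts]
    out.drop(columns=[c for c in ("maturity",) if c in out.columns]).to_csv(path, index=False)


def read_sensor_series(path: str | Path, tag_id: str | None = None) -> SensorSeries:
    """Read a DST depth/temperature series (nominal 90-s cadence).

    Small negative depths in (-1, 0) m are sensor noise and clipped to 0;
    depths below -1 m are rejected.  Non-monotone timestamps are a hard
    error naming the first offending record.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SENSOR_COLUMNS, path)
    df["timestamp"] = _parse_times(df["timestamp"])
    if df["timestamp"].isna().any():
        first = int(df.index[df["timestamp"].isna()][0])
        raise ValueError(f"{path}: unparseable timestamp at record {first}")
    dt = df["timestamp"].diff().dt.total_seconds()
    if (dt <= 0).any():
        first = int(df.index[dt <= 0][0])
        raise ValueError(f"{path}: non-monotone timestamp at record {first}")
    depth = pd.to_numeric(df["depth_m"])
    if (depth < -1.0).any():
        raise ValueError(f"{path}: depth below -1 m at record "
                         f"{int(df.index[depth < -1.0][0])}")
    depth = depth.clip(lower=0.0)
    out = pd.DataFrame({
        "timestamp": df["timestamp"],
        "depth_m": depth,
        "temperature_c": pd.to_numeric(df["temperature_c"]),
    })
    if tag_id is None:
        stem = path.stem
        tag_id = stem[4:] if stem.startswith("dst_") else stem
    series = SensorSeries(tag_id=tag_id, data=out.reset_index(drop=True))
    log.info("%s: %d records, median cadence %.0f s", path, len(out), series.median_dt_s)
    return series


def write_sensor_series(series: SensorSeries, path: str | Path) -> None:
    out = series.data.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(_TIME_FMT)
    out["depth_m"] = out["depth_m"].map(lambda v: f"{v:.3f}")
    out["temperature_c"] = out["temperature_c"].map(lambda v: f"{v:.3f}")
    out.to_csv(path, index=False)


def aggregate_hourly(series: SensorSeries) -> pd.DataFrame:
    """Reduce a 90-s sensor series to hourly observations.

    Hour bins are clock-aligned half-open [h, h+1).  Per hour with at least
    one record: ``z_max`` (max depth, the most constraining value against
    bathymetry), ``z_mean``, ``t_mean`` and the record count.  Empty hours
    are simply absent.
    """
    if series.data.empty:
        raise ValueError("cannot aggregate an empty sensor series")
    df = series.data
    hour = df["timestamp"].dt.floor("h")
    g = df.groupby(hour, sort=True)
    out = pd.DataFrame({
        "hour": list(g.groups.keys()),
        "z_max": g["depth_m"].max().values,
        "z_mean": g["depth_m"].mean().values,
        "t_mean": g["temperature_c"].mean().values,
        "n_records": g.size().values,
    })
    return out.reset_index(drop=True)
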