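"""Synthetic study generator: environment, fish tracks, archival records,
receiver network and acoustic detections with known ground truth.

The generator emulates a coastal double-tagging campaign: a regular
~2 x 2 km lat/lon grid with a land strip along its eastern edge, smooth
bathymetry deepening offshore, an M2 tidal sea-surface height, a
temperature field with a zonal gradient plus seasonal and diel cycles on
vertical levels, fish following a Brownian random walk rejected off land,
90-s depth/temperature archival records, and receivers that log
exponential-gap pings while a fish is inside their detection range.
False detections (random times, near-threshold signal-to-noise) are
injected at a configurable per-receiver-day rate and labelled, so
filtering performance can be measured against truth.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec, ReferenceFields, haversine_km
from .io import (SensorSeries, write_detections, write_fish, write_receivers,
                 write_sensor_series)

__all__ = ["ScenarioConfig", "Scenario", "make_environment", "simulate_track",
           "simulate_dst", "simulate_detections", "generate_scenario",
           "write_scenario"]


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic study (defaults: a one-month coastal
    campaign on a ~2 km grid with a small receiver array)."""

    # grid extent and step (degrees); ~2 x 2 km cells at 48 N
    lon_min: float = -5.8
    lon_max: float = -4.6
    lat_min: float = 47.8
    lat_max: float = 48.6
    lon_step: float = 0.027
    lat_step: float = 0.018
    # coastline / bathymetry
    coast_offset_deg: float = 0.15     # mean distance of the coast from lon_max
    coast_wiggle_deg: float = 0.05     # sinusoidal coastline amplitude
    max_depth_m: float = 120.0
    level_depths_m: tuple = (0.0, 10.0, 25.0, 50.0, 100.0)
    # temperature field
    t0_c: float = 14.0                 # surface reference at the western edge
    zonal_gradient_c_per_deg: float = 0.5
    seasonal_amp_c: float = 2.0
    diel_amp_c: float = 0.3
    lapse_c_per_m: float = 0.02
    # tide
    tide_amp_m: float = 1.5
    tide_period_h: float = 12.42
    # campaign
    start: str = "2022-06-15"
    duration_days: int = 30
    n_fish: int = 20
    double_tag_fraction: float = 0.6
    recovery_fraction: float = 0.5     # of double-tagged fish recaptured
    bay_fraction: float = 0.5          # released at the short-term survival bay
    release_offset_days: float = 1.0   # release after receivers start listening
    length_mean_mm: float = 480.0
    length_sd_mm: float = 60.0
    # movement / behaviour
    sigma_true: float = 1.0            # Brownian sd, cells per sqrt-hour
    # hourly depth as a fraction of the water column; seabed-biased
    # (bentho-demersal habit)
    depth_beta_a: float = 5.0
    depth_beta_b: float = 2.0
    # sensors
    dst_cadence_s: float = 90.0
    depth_noise_m: float = 0.3
    temp_noise_c: float = 0.1
    # acoustics
    n_receivers: int = 8
    detection_range_m: float = 400.0
    ping_interval_s: float = 180.0
    detection_model: str = "disk"      # "disk" or "logistic"
    logistic_scale_m: float = 50.0
    false_detection_rate: float = 0.05  # per receiver-day, per tag
    true_snr_mean: float = 20.0
    true_snr_sd: float = 5.0
    false_snr_mean: float = 3.5
    false_snr_sd: float = 1.2
    tag_protocol: str = "OPi"
    receiver_protocol: str = "OPi"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_true", "false_detection_rate", "depth_noise_m",
                     "temp_noise_c", "tide_amp_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def t_start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start)

    @property
    def t_end(self) -> pd.Timestamp:
        return self.t_start + pd.Timedelta(days=self.duration_days)


@dataclass
class Scenario:
    """All generated inputs plus ground truth."""

    cfg: ScenarioConfig
    grid: GridSpec
    fields: ReferenceFields
    receivers: pd.DataFrame
    fish: pd.DataFrame
    detections: pd.DataFrame            # includes truth column ``is_true``
    dst: dict[str, SensorSeries] = field(default_factory=dict)
    tracks: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def temporary_stations(self) -> tuple[str, str]:
        return ("Temp_A", "Temp_B")


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def make_environment(cfg: ScenarioConfig) -> tuple[GridSpec, ReferenceFields]:
    """Build the grid and environmental reference fields.

    Land occupies the strip east of a sinusoidal coastline; depth ramps up
    offshore towards ``max_depth_m`` with a zonal channel.  Temperature is
    NaN on land and below the local seabed.
    """
    lon = np.arange(cfg.lon_min, cfg.lon_max + 1e-9, cfg.lon_step)
    lat = np.arange(cfg.lat_min, cfg.lat_max + 1e-9, cfg.lat_step)
    lon2d, lat2d = np.meshgrid(lon, lat)

    coast_lon = (cfg.lon_max - cfg.coast_offset_deg
                 + cfg.coast_wiggle_deg
                 * np.sin(2.0 * np.pi * (lat2d - cfg.lat_min)
                          / (cfg.lat_max - cfg.lat_min)))
    west_of_coast = coast_lon - lon2d            # >0 at sea
    sea = west_of_coast > 0.0
    width = cfg.coast_offset_deg + (cfg.lon_max - cfg.lon_min)
    frac = np.clip(west_of_coast / width, 0.0, 1.0)
    channel = 30.0 * np.exp(-((lat2d - 0.5 * (cfg.lat_min + cfg.lat_max))
                              / 0.08) ** 2) * frac
    bathy = np.where(sea, cfg.max_depth_m * frac ** 0.8 + channel + 5.0, np.nan)

    grid = GridSpec(lon=lon, lat=lat, sea_mask=sea)

    n_hours = int(cfg.duration_days * 24) + 25   # one day of margin
    times = pd.date_range(cfg.t_start, periods=n_hours, freq="h")
    th = np.arange(n_hours, dtype=float)

    phase = 2.0 * np.pi * (lon2d - cfg.lon_min) / (cfg.lon_max - cfg.lon_min) * 0.5
    ssh = (cfg.tide_amp_m
           * np.sin(2.0 * np.pi * th[:, None, None] / cfg.tide_period_h
                    + phase[None, :, :])).astype(np.float32)
    ssh = np.where(sea[None, :, :], ssh, np.nan)

    lv = np.asarray(cfg.level_depths_m, dtype=float)
    doy = times.dayofyear.values.astype(float)
    hod = times.hour.values.astype(float)
    seasonal = cfg.seasonal_amp_c * np.sin(2.0 * np.pi * (doy - 110.0) / 365.0)
    diel = cfg.diel_amp_c * np.sin(2.0 * np.pi * hod / 24.0)
    temp = (cfg.t0_c
            + cfg.zonal_gradient_c_per_deg * (lon2d - cfg.lon_min)[None, None, :, :]
            + seasonal[:, None, None, None] * np.exp(-lv / 40.0)[None, :, None, None]
            + diel[:, None, None, None] * np.exp(-lv / 10.0)[None, :, None, None]
            - cfg.lapse_c_per_m * lv[None, :, None, None]).astype(np.float32)
    below_bed = lv[None, :, None, None] > np.nan_to_num(bathy, nan=0.0)[None, None, :, :]
    temp = np.where(below_bed | ~sea[None, None, :, :], np.nan, temp)

    fields = ReferenceFields.from_arrays(
        grid, times.values, lv, np.nan_to_num(bathy, nan=0.0), ssh, temp)
    return grid, fields


# ---------------------------------------------------------------------------
# movement and sensors
# ---------------------------------------------------------------------------

def simulate_track(cfg: ScenarioConfig, grid: GridSpec,
                   release_lonlat: tuple[float, float],
                   times: pd.DatetimeIndex,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Hourly Brownian random-walk track; steps landing on land (or off
    the grid) are resampled.  Positions are continuous lon/lat with the
    occupied cell indices alongside."""
    iy0, ix0 = grid.cell_index(*release_lonlat)
    if not grid.sea_mask[iy0, ix0]:
        raise ValueError("release position is on land")
    x = (release_lonlat[0] - grid.lon[0]) / grid.lon_step
    y = (release_lonlat[1] - grid.lat[0]) / grid.lat_step
    nx, ny = grid.lon.size, grid.lat.size
    xs = np.empty(len(times))
    ys = np.empty(len(times))
    xs[0], ys[0] = x, y
    for t in range(1, len(times)):
        for _ in range(200):
            dx, dy = rng.normal(0.0, cfg.sigma_true, size=2)
            xn, yn = xs[t - 1] + dx, ys[t - 1] + dy
            ixn, iyn = int(round(xn)), int(round(yn))
            if 0 <= ixn < nx and 0 <= iyn < ny and grid.sea_mask[iyn, ixn]:
                break
        else:  # boxed in: stay put
            xn, yn = xs[t - 1], ys[t - 1]
        xs[t], ys[t] = xn, yn
    ix = np.rint(xs).astype(int)
    iy = np.rint(ys).astype(int)
    return pd.DataFrame({"time": times,
                         "lon": grid.lon[0] + xs * grid.lon_step,
                         "lat": grid.lat[0] + ys * grid.lat_step,
                         "ix": ix, "iy": iy})


def simulate_dst(track: pd.DataFrame, fields: ReferenceFields,
                 cfg: ScenarioConfig, rng: np.random.Generator,
                 tag_id: str = "DST", death_time=None) -> SensorSeries:
    """90-s depth/temperature records along a track.

    Each hour draws a depth-behaviour fraction from a Beta distribution;
    recorded depth is that fraction of the local water column plus noise,
    never exceeding the water column.  Temperature is the reference field
    at the occupied cell interpolated to the recorded depth, plus noise.
    After ``death_time`` the tag floats: near-zero constant depth.
    """
    lv = fields.level_depths
    temp4d = fields.ds["temperature"].values
    bathy = fields.ds["bathymetry"].values
    ssh3d = fields.ds["ssh"].values
    per_hour = max(1, int(round(3600.0 / cfg.dst_cadence_s)))
    rows_t, rows_z, rows_c = [], [], []
    for _, row in track.iterrows():
        it = fields.time_index(row["time"])
        iy, ix = int(row["iy"]), int(row["ix"])
        wd = float(bathy[iy, ix] + ssh3d[it, iy, ix])
        frac = rng.beta(cfg.depth_beta_a, cfg.depth_beta_b)
        offs = np.arange(per_hour) * cfg.dst_cadence_s
        ts = row["time"] + pd.to_timedelta(offs, unit="s")
        dead = death_time is not None and row["time"] >= death_time
        if dead:
            z = np.clip(0.3 + rng.normal(0.0, 0.05, per_hour), 0.0, wd)
        else:
            z = np.clip(frac * wd + rng.normal(0.0, cfg.depth_noise_m, per_hour),
                        0.0, wd)
        prof = temp4d[it, :, iy, ix].astype(float)
        for k in range(1, prof.size):   # fill below-seabed levels downward
            if not np.isfinite(prof[k]):
                prof[k] = prof[k - 1]
        tc = np.interp(z, lv, prof) + rng.normal(0.0, cfg.temp_noise_c, per_hour)
        rows_t.append(ts)
        rows_z.append(z)
        rows_c.append(tc)
    data = pd.DataFrame({
        "timestamp": pd.DatetimeIndex(np.concatenate([t.values for t in rows_t])),
        "depth_m": np.concatenate(rows_z),
        "temperature_c": np.concatenate(rows_c),
    })
    return SensorSeries(tag_id=tag_id, data=data)


def _protocol_compatible(tag_protocol: str, receiver_protocol: str) -> bool:
    # open-protocol receivers decode both code maps; legacy receivers
    # decode only legacy tags
    if receiver_protocol == "OPi":
        return tag_protocol in ("OPi", "R64K")
    if receiver_protocol == "R64K":
        return tag_protocol == "R64K"
    return False


def simulate_detections(track: pd.DataFrame, receivers: pd.DataFrame,
                        cfg: ScenarioConfig, rng: np.random.Generator,
                        tag_id: str, tag_protocol: str | None = None,
                        ) -> pd.DataFrame:
    """Acoustic detections of one fish, with truth labels.

    While the fish is inside a compatible active receiver's range, pings
    arrive with exponential gaps (mean ``ping_interval_s``) and are
    detected with probability 1 inside the detection radius (hard disk;
    a logistic range curve is available via ``detection_model``).  False
    detections are injected per receiver as a Poisson process over the
    deployment at ``false_detection_rate`` per day, with near-threshold
    signal-to-noise ratios, labelled ``is_true = False``.
    """
    tag_protocol = tag_protocol or cfg.tag_protocol
    rows = []
    for _, r in receivers.iterrows():
        if not _protocol_compatible(tag_protocol, r["protocol"]):
            continue
        d_km = haversine_km(track["lon"].values, track["lat"].values,
                            r["lon"], r["lat"])
        active = (track["time"] >= r["start"]) & (track["time"] < r["end"])
        if cfg.detection_model == "logistic":
            p_det = 1.0 / (1.0 + np.exp((d_km * 1000.0 - r["detection_range_m"])
                                        / cfg.logistic_scale_m))
        else:
            p_det = (d_km * 1000.0 <= r["detection_range_m"]).astype(float)
        for hr_idx in np.nonzero(active.values & (p_det > 1e-6))[0]:
            t0 = track["time"].iloc[hr_idx]
            t = rng.exponential(cfg.ping_interval_s)
            while t < 3600.0:
                if rng.random() < p_det[hr_idx]:
                    rows.append({
                        "tag_id": tag_id,
                        "timestamp": t0 + pd.Timedelta(seconds=round(t)),
                        "receiver_id": r["receiver_id"], "station": r["station"],
                        "lon": r["lon"], "lat": r["lat"],
                        "snr": rng.normal(cfg.true_snr_mean, cfg.true_snr_sd),
                        "is_true": True})
                t += rng.exponential(cfg.ping_interval_s)
    # injected false detections: uniform over the deployment window
    # (only receivers that can decode this tag's protocol can collide)
    for _, r in receivers.iterrows():
        if not _protocol_compatible(tag_protocol, r["protocol"]):
            continue
        days = (r["end"] - r["start"]).total_seconds() / 86400.0
        n_false = rng.poisson(cfg.false_detection_rate * days)
        for _ in range(n_false):
            t = r["start"] + pd.Timedelta(
                seconds=round(rng.uniform(0.0, days * 86400.0)))
            rows.append({"tag_id": tag_id, "timestamp": t,
                         "receiver_id": r["receiver_id"], "station": r["station"],
                         "lon": r["lon"], "lat": r["lat"],
                         "snr": rng.normal(cfg.false_snr_mean, cfg.false_snr_sd),
                         "is_true": False})
    df = pd.DataFrame(rows, columns=["tag_id", "timestamp", "receiver_id",
                                     "station", "lon", "lat", "snr", "is_true"])
    return df.sort_values(["tag_id", "timestamp"], kind="mergesort"
                          ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def _place_receivers(cfg: ScenarioConfig, grid: GridSpec,
                     fields: ReferenceFields) -> pd.DataFrame:
    """Receiver stations on coastal sea cells (15-80 m deep), spread in
    latitude, plus the two temporary short-term-survival stations placed
    700 m apart in the 'bay' nearest the first station."""
    bathy = fields.ds["bathymetry"].values
    cand = np.argwhere(grid.sea_mask & (bathy > 15.0) & (bathy < 80.0))
    # keep candidates within ~12 km of the coast: easternmost per row
    best = {}
    for iy, ix in cand:
        if iy not in best or ix > best[iy]:
            best[iy] = ix
    rows_iy = sorted(best)
    picks = [rows_iy[i] for i in
             np.linspace(2, len(rows_iy) - 3, cfg.n_receivers).astype(int)]
    recs = []
    for j, iy in enumerate(picks):
        ix = best[iy] - 1
        lon, lat = grid.lon[ix], grid.lat[iy]
        recs.append({"receiver_id": f"R{j + 1:03d}", "station": f"Station_{j + 1}",
                     "lon": lon, "lat": lat,
                     "start": cfg.t_start, "end": cfg.t_end,
                     "detection_range_m": cfg.detection_range_m,
                     "protocol": cfg.receiver_protocol})
    # temporary bay stations near station 1
    bay_lon, bay_lat = recs[0]["lon"] - 2 * grid.lon_step, recs[0]["lat"]
    for name, dlon in (("Temp_A", 0.0), ("Temp_B", 0.0095)):
        recs.append({"receiver_id": f"R_{name}", "station": name,
                     "lon": bay_lon + dlon, "lat": bay_lat,
                     "start": cfg.t_start,
                     "end": cfg.t_start + pd.Timedelta(days=min(10, cfg.duration_days)),
                     "detection_range_m": cfg.detection_range_m,
                     "protocol": cfg.receiver_protocol})
    return pd.DataFrame(recs)


def generate_scenario(cfg: ScenarioConfig | None = None) -> Scenario:
    """Generate the full synthetic study with ground truth (deterministic
    under ``cfg.seed``)."""
    cfg = cfg or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    grid, fields = make_environment(cfg)
    receivers = _place_receivers(cfg, grid, fields)
    stations = receivers[~receivers["station"].isin(["Temp_A", "Temp_B"])]
    bay = receivers[receivers["station"] == "Temp_A"].iloc[0]

    release_time = cfg.t_start + pd.Timedelta(days=cfg.release_offset_days)
    end = cfg.t_end
    n_hours = int((end - release_time) / pd.Timedelta(hours=1))
    times = pd.date_range(release_time, periods=n_hours, freq="h")

    n_double = int(round(cfg.n_fish * cfg.double_tag_fraction))
    n_bay = int(round(cfg.n_fish * cfg.bay_fraction))
    fish_rows, detections, dst, tracks = [], [], {}, {}
    for i in range(cfg.n_fish):
        tag = f"AT{i + 1:03d}"
        double = i < n_double
        recovered = double and (i < int(round(n_double * cfg.recovery_fraction)))
        in_bay = i < n_bay
        if in_bay:
            rel_lon, rel_lat = bay["lon"] + 0.004, bay["lat"]
        else:
            r = stations.iloc[int(rng.integers(1, len(stations)))]
            rel_lon, rel_lat = r["lon"] - 2 * grid.lon_step, r["lat"]
        track = simulate_track(cfg, grid, (rel_lon, rel_lat), times, rng)
        tracks[tag] = track
        detections.append(simulate_detections(track, receivers, cfg, rng, tag))
        length = float(np.clip(rng.normal(cfg.length_mean_mm, cfg.length_sd_mm),
                               350.0, 650.0))
        row = {"acoustic_tag_id": tag,
               "archival_tag_id": f"DST{i + 1:03d}" if double else "",
               "total_length_mm": round(length),
               "release_time": release_time,
               "release_lon": rel_lon, "release_lat": rel_lat,
               "recapture_time": pd.NaT, "recapture_lon": np.nan,
               "recapture_lat": np.nan, "in_bay": in_bay}
        if double:
            dst[tag] = simulate_dst(track, fields, cfg, rng, tag_id=f"DST{i + 1:03d}")
        if recovered:
            row["recapture_time"] = track["time"].iloc[-1]
            row["recapture_lon"] = track["lon"].iloc[-1]
            row["recapture_lat"] = track["lat"].iloc[-1]
        fish_rows.append(row)

    fish = pd.DataFrame(fish_rows)
    fish["maturity"] = np.where(fish["total_length_mm"] >= 437.0,
                                "mature", "immature")
    dets = pd.concat(detections, ignore_index=True) if detections else \
        pd.DataFrame(columns=["tag_id", "timestamp", "receiver_id", "station",
                              "lon", "lat", "snr", "is_true"])
    dets = dets.sort_values(["tag_id", "timestamp"], kind="mergesort"
                            ).reset_index(drop=True)
    return Scenario(cfg=cfg, grid=grid, fields=fields, receivers=receivers,
                    fish=fish, detections=dets, dst=dst, tracks=tracks)


def write_scenario(sc: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write all pipeline input files plus ground truth under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = outdir / "truth"
    truth.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["detections"] = outdir / "detections.csv"
    write_detections(sc.detections.drop(columns=["is_true"]), paths["detections"])
    paths["receivers"] = outdir / "receivers.csv"
    write_receivers(sc.receivers, paths["receivers"])
    paths["fish"] = outdir / "fish.csv"
    write_fish(sc.fish.drop(columns=["in_bay"]), paths["fish"])
    paths["fields"] = outdir / "fields.nc"
    sc.fields.to_netcdf(paths["fields"])
    for tag, series in sc.dst.items():
        p = outdir / f"dst_{series.tag_id}.csv"
        write_sensor_series(series, p)
        paths[f"dst_{tag}"] = p
    # ground truth
    labels = sc.detections.copy()
    write_detections(labels, truth / "detections_labelled.csv")
    for tag, tr in sc.tracks.items():
        tr.to_csv(truth / f"track_{tag}.csv", index=False)
    paths["truth"] = truth
    return paths
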