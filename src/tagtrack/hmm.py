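"""Gridded hidden-Markov geolocation.

The fish's hourly position is a hidden state on a regular lat/lon sea grid.
Emission likelihoods come from three sources and are combined by
elementwise product:

- **depth**: a cell is feasible if its instantaneous water column
  (bathymetry + sea-surface height) can accommodate the hour's maximum
  recorded depth, with a Gaussian penalty on any shortfall;
- **temperature**: Gaussian mismatch between the hour's mean recorded
  temperature and the reference temperature interpolated vertically to the
  hour's mean depth;
- **acoustic detections**: an hour with a detection pins the state to the
  detecting receiver's cell(s); an hour without detections excludes the
  cells within range of every active receiver.

Movement is an isotropic Brownian random walk, discretised as a truncated
Gaussian kernel (sigma in grid-cell units per square-root hour).  At land
boundaries the kernel is masked and renormalised so probability is
conserved.  Forward-backward smoothing yields the posterior position
distribution per hour; the diffusion coefficient sigma is estimated by
maximising the marginal likelihood with a bounded scalar search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve as _ndconvolve
from scipy.optimize import minimize_scalar

from .grid import GridSpec, ReferenceFields, haversine_km

log = logging.getLogger(__name__)

__all__ = [
    "InfeasibleTrackError", "LikelihoodStack", "MovementKernel",
    "PosteriorStack", "Track", "SigmaEstimate",
    "depth_likelihood", "temperature_likelihood", "acoustic_likelihood",
    "combine_likelihoods", "movement_kernel", "forward_backward",
    "forward_loglik", "estimate_sigma", "extract_track", "daily_mean_track",
    "track_distance", "track_sensitivity",
]


class InfeasibleTrackError(ValueError):
    """No grid cell is consistent with the observations at some hour."""


@dataclass
class LikelihoodStack:
    """Non-negative emission weights per (hour, cell); zero on land."""

    grid: GridSpec
    times: pd.DatetimeIndex
    values: np.ndarray  # (T, n_lat, n_lon)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = pd.DatetimeIndex(self.times)
        if self.values.shape != (len(self.times),) + self.grid.shape:
            raise ValueError("likelihood values shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("likelihood values must be non-negative")

    def check_feasible(self) -> None:
        sums = self.values.reshape(len(self.times), -1).sum(axis=1)
        bad = np.nonzero(sums == 0.0)[0]
        if bad.size:
            raise InfeasibleTrackError(
                f"all-zero likelihood slice at hour index {bad[0]} "
                f"({self.times[bad[0]]})")


@dataclass
class MovementKernel:
    """Truncated discrete Gaussian step kernel (cell units per sqrt-hour)."""

    sigma: float
    array: np.ndarray = field(repr=False)

    @property
    def radius(self) -> int:
        return self.array.shape[0] // 2


@dataclass
class PosteriorStack:
    """Smoothed state probabilities per (hour, cell); each slice sums to 1."""

    grid: GridSpec
    times: pd.DatetimeIndex
    probs: np.ndarray  # (T, n_lat, n_lon)


@dataclass
class Track:
    """Extracted positions per hour: posterior mean and mode, and the
    positional spread (root mean square distance from the mean, km)."""

    data: pd.DataFrame  # time, lon_mean, lat_mean, lon_mode, lat_mode, sd_km

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SigmaEstimate:
    sigma_hat: float
    log_likelihood: float
    profile: pd.DataFrame  # sigma, loglik
    at_boundary: bool = False


# ---------------------------------------------------------------------------
# emission likelihoods
# ---------------------------------------------------------------------------

def _hours(obs: pd.DataFrame) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(obs["hour"])


def depth_likelihood(obs: pd.DataFrame, fields: ReferenceFields,
                     sigma_z: float = 5.0) -> LikelihoodStack:
    """Depth feasibility weights.

    A cell whose water column (bathymetry + ssh) is at least
    ``z_max - sigma_z`` gets weight 1; shallower cells are penalised by
    ``exp(-(z_max - depth)^2 / (2 sigma_z^2))``.  Land cells are 0.
    """
    grid = fields.grid
    times = _hours(obs)
    sea = grid.sea_mask
    bathy = fields.ds["bathymetry"].values
    ssh = fields.ds["ssh"].values
    out = np.zeros((len(times),) + grid.shape)
    for k, (hour, z_max) in enumerate(zip(times, obs["z_max"].values)):
        it = fields.time_index(hour)  # KeyError names the missing hour
        wd = bathy + ssh[it]
        shortfall = z_max - wd
        w = np.where(shortfall <= sigma_z, 1.0,
                     np.exp(-shortfall ** 2 / (2.0 * sigma_z ** 2)))
        out[k] = np.where(sea, w, 0.0)
    return LikelihoodStack(grid=grid, times=times, values=out)


def _temp_at_depth(temp3d: np.ndarray, level_depths: np.ndarray,
                   z: float) -> np.ndarray:
    """Reference temperature interpolated vertically to depth ``z``.

    Levels below the local seabed are NaN in the reference field; they are
    filled downward so a cell shallower than ``z`` yields its deepest
    available value.
    """
    filled = temp3d.copy()
    for k in range(1, filled.shape[0]):
        nan = ~np.isfinite(filled[k])
        filled[k][nan] = filled[k - 1][nan]
    z = float(np.clip(z, level_depths[0], level_depths[-1]))
    k = int(np.searchsorted(level_depths, z, side="right") - 1)
    k = min(k, len(level_depths) - 2)
    w = (z - level_depths[k]) / (level_depths[k + 1] - level_depths[k])
    return (1.0 - w) * filled[k] + w * filled[k + 1]


def temperature_likelihood(obs: pd.DataFrame, fields: ReferenceFields,
                           sigma_t: float = 1.0) -> LikelihoodStack:
    """Gaussian (unnormalised) weights for the mismatch between recorded
    mean temperature and the reference temperature at the recorded mean
    depth.  An hour where no sea cell is within numerical reach of the
    record raises with a diagnostic of the smallest mismatch."""
    grid = fields.grid
    times = _hours(obs)
    sea = grid.sea_mask
    temp = fields.ds["temperature"].values
    lv = fields.level_depths
    out = np.zeros((len(times),) + grid.shape)
    for k, (hour, z_mean, t_mean) in enumerate(
            zip(times, obs["z_mean"].values, obs["t_mean"].values)):
        it = fields.time_index(hour)
        t_ref = _temp_at_depth(temp[it], lv, z_mean)
        delta = t_mean - t_ref
        w = np.exp(-np.square(delta) / (2.0 * sigma_t ** 2))
        w = np.where(np.isfinite(w) & sea, np.nan_to_num(w), 0.0)
        if w.sum() == 0.0:
            dmin = np.nanmin(np.abs(delta[sea]))
            raise InfeasibleTrackError(
                f"temperature likelihood is zero everywhere at {hour}; "
                f"min |dT| on sea cells = {dmin:.2f} C")
        out[k] = w
    return LikelihoodStack(grid=grid, times=times, values=out)


def receiver_coverage(receivers: pd.DataFrame, grid: GridSpec,
                      subsample: int = 8) -> dict[str, np.ndarray]:
    """Fraction of each grid cell covered by every receiver's detection
    disk (0..1 per cell).

    The detection range (hundreds of metres) is typically smaller than a
    grid cell (~2 km), so a cell is usually only partially covered; the
    fraction is estimated on a ``subsample x subsample`` lattice of points
    inside the cell.  The cell containing the receiver always gets a
    strictly positive fraction.
    """
    offs = (np.arange(subsample) + 0.5) / subsample - 0.5
    out = {}
    for _, r in receivers.iterrows():
        cov = np.zeros(grid.shape)
        rad_km = r["detection_range_m"] / 1000.0
        # candidate cells: bounding box around the disk
        iy0, ix0 = grid.cell_index(r["lon"], r["lat"])
        dlat = rad_km / 111.195 / grid.lat_step + 1
        dlon = rad_km / (111.195 * np.cos(np.radians(r["lat"]))) / grid.lon_step + 1
        for iy in range(max(0, int(iy0 - dlat)), min(grid.lat.size, int(iy0 + dlat) + 1)):
            for ix in range(max(0, int(ix0 - dlon)), min(grid.lon.size, int(ix0 + dlon) + 1)):
                plon = grid.lon[ix] + offs * grid.lon_step
                plat = grid.lat[iy] + offs * grid.lat_step
                pl, pt = np.meshgrid(plon, plat)
                d = haversine_km(pl, pt, r["lon"], r["lat"])
                cov[iy, ix] = float((d <= rad_km).mean())
        if cov[iy0, ix0] == 0.0:  # range smaller than the point lattice
            cov[iy0, ix0] = min(1.0, np.pi * rad_km ** 2
                                / (grid.cell_size_km()[0] * grid.cell_size_km()[1]))
        out[r["receiver_id"]] = cov
    return out


def acoustic_likelihood(dets: pd.DataFrame, receivers: pd.DataFrame,
                        grid: GridSpec, times: pd.DatetimeIndex,
                        nondetection_value: float = 1.0) -> LikelihoodStack:
    """Presence/absence weights from acoustic detections.

    For an hour with detections the weight is positive only on the
    cell(s) overlapping the detection disk of *every* detecting receiver,
    in proportion to the covered fraction of the cell (simultaneous
    detections at distant stations have an empty intersection and raise),
    and 0 elsewhere.  For an hour without detections each cell gets
    ``nondetection_value`` times the probability of escaping every active
    receiver, ``prod(1 - coverage)`` — in particular 0 for cells fully
    inside an active detection disk.  With no active receiver the slice
    is uniform.
    """
    times = pd.DatetimeIndex(times)
    coverage = receiver_coverage(receivers, grid)
    recv = receivers.set_index("receiver_id")
    sea = grid.sea_mask.astype(float)
    if len(dets):
        d = dets.copy()
        d["hour"] = pd.DatetimeIndex(d["timestamp"]).floor("h")
        by_hour = dict(tuple(d.groupby("hour")))
    else:
        by_hour = {}
    out = np.empty((len(times),) + grid.shape)
    for k, hour in enumerate(times):
        h_end = hour + pd.Timedelta(hours=1)
        active = recv[(recv["start"] < h_end) & (recv["end"] > hour)]
        g = by_hour.get(hour)
        if g is not None and len(g):
            w = np.ones(grid.shape)
            for rid in g["receiver_id"].unique():
                if rid not in recv.index or rid not in active.index:
                    raise ValueError(
                        f"detection at receiver {rid!r} outside its deployment "
                        f"at {hour} (should have been removed by QC)")
                w *= coverage[rid]
            slice_ = w * sea
            if slice_.sum() == 0.0:
                raise InfeasibleTrackError(
                    f"conflicting simultaneous detections at {hour}: "
                    "detection disks do not intersect")
            out[k] = slice_
        elif len(active):
            w = np.full(grid.shape, nondetection_value)
            for rid in active.index:
                w *= 1.0 - coverage[rid]
            out[k] = w * sea
        else:
            out[k] = sea
    return LikelihoodStack(grid=grid, times=times, values=out)


def combine_likelihoods(*stacks: LikelihoodStack,
                        release: tuple[float, float] | None = None,
                        recapture: tuple[float, float] | None = None,
                        ) -> LikelihoodStack:
    """Elementwise product of aligned likelihood stacks, with optional
    positional anchors.

    The release (lon, lat) replaces the first slice by a one-hot at the
    release cell; a known recapture position multiplies the last slice by
    a one-hot at the recapture cell.  Any all-zero slice raises naming the
    hour and the first contributing stack that is zero there.
    """
    if not stacks:
        raise ValueError("need at least one likelihood stack")
    ref = stacks[0]
    for s in stacks[1:]:
        if not ref.times.equals(s.times):
            raise ValueError("likelihood stacks have mismatched time axes")
    values = np.ones_like(ref.values)
    for s in stacks:
        values *= s.values
    grid = ref.grid
    if release is not None:
        iy, ix = grid.cell_index(*release)
        one = np.zeros(grid.shape)
        one[iy, ix] = 1.0
        values[0] = one
    if recapture is not None:
        iy, ix = grid.cell_index(*recapture)
        one = np.zeros(grid.shape)
        one[iy, ix] = 1.0
        anchored = values[-1] * one
        if anchored.sum() == 0.0:
            # emission weight vanished in the recapture cell (e.g. a final-
            # hour detection one cell away); the recapture position is a
            # direct observation, so it overrides the emissions there
            log.warning("recapture anchor conflicts with the final emission "
                        "slice; replacing it")
            anchored = one
        values[-1] = anchored
    sums = values.reshape(len(ref.times), -1).sum(axis=1)
    bad = np.nonzero(sums == 0.0)[0]
    if bad.size:
        t = int(bad[0])
        culprit = next((i for i, s in enumerate(stacks)
                        if s.values[t].sum() == 0.0), None)
        raise InfeasibleTrackError(
            f"combined likelihood is all-zero at hour index {t} "
            f"({ref.times[t]}); first all-zero input stack: {culprit}")
    return LikelihoodStack(grid=grid, times=ref.times, values=values)


# ---------------------------------------------------------------------------
# movement model and smoothing
# ---------------------------------------------------------------------------

def movement_kernel(sigma: float, truncation: float = 4.0) -> MovementKernel:
    """Discrete isotropic Gaussian displacement kernel, truncated at
    ``truncation * sigma`` cells and renormalised to unit mass."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = max(1, int(np.ceil(truncation * sigma)))
    if sigma < 0.05:
        log.info("sigma=%g cells: kernel is effectively a delta", sigma)
    ax = np.arange(-radius, radius + 1, dtype=float)
    dx, dy = np.meshgrid(ax, ax)
    with np.errstate(under="ignore"):
        k = np.exp(-(dx ** 2 + dy ** 2) / (2.0 * sigma ** 2))
    k /= k.sum()
    return MovementKernel(sigma=float(sigma), array=k)


def _conv(p: np.ndarray, k: np.ndarray) -> np.ndarray:
    return _ndconvolve(p, k, mode="constant", cval=0.0)


class _Stepper:
    """One application of the land-masked, renormalised Brownian kernel.

    The effective transition matrix is
    ``T[i -> j] = K(j - i) * sea(j) / Z(i)`` with ``Z(i)`` the kernel mass
    landing on sea from cell i, so each predict step conserves probability
    exactly (reflecting-like behaviour at the coast).
    """

    def __init__(self, kernel: MovementKernel, sea: np.ndarray):
        self.k = kernel.array
        self.sea = sea
        z = _conv(sea.astype(float), self.k)
        self.z = np.where(sea & (z > 0), z, 1.0)

    def predict(self, p: np.ndarray) -> np.ndarray:
        return np.where(self.sea, _conv(p / self.z, self.k), 0.0)

    def back(self, m: np.ndarray) -> np.ndarray:
        return np.where(self.sea, _conv(np.where(self.sea, m, 0.0), self.k)
                        / self.z, 0.0)


def forward_loglik(L: LikelihoodStack, kernel: MovementKernel,
                   prior: np.ndarray | None = None) -> float:
    """Log marginal likelihood from the forward filter alone."""
    _, _, ll = _forward(L, kernel, prior)
    return ll


def _forward(L: LikelihoodStack, kernel: MovementKernel,
             prior: np.ndarray | None):
    grid = L.grid
    sea = grid.sea_mask
    step = _Stepper(kernel, sea)
    T = len(L.times)
    if prior is None:
        prior = sea / sea.sum()
    alphas = np.empty_like(L.values)
    ll = 0.0
    p = prior * L.values[0]
    c = p.sum()
    if c == 0.0:
        raise InfeasibleTrackError("zero normaliser at hour index 0")
    alphas[0] = p / c
    ll += np.log(c)
    for t in range(1, T):
        p = step.predict(alphas[t - 1]) * L.values[t]
        c = p.sum()
        if c == 0.0:
            raise InfeasibleTrackError(f"zero normaliser at hour index {t} "
                                       f"({L.times[t]})")
        alphas[t] = p / c
        ll += np.log(c)
    return alphas, step, float(ll)


def forward_backward(L: LikelihoodStack, kernel: MovementKernel,
                     prior: np.ndarray | None = None,
                     ) -> tuple[PosteriorStack, float]:
    """Grid HMM filter-smoother.

    Forward pass: predict with the movement kernel, update with the
    emission likelihood, normalise (accumulating the log marginal
    likelihood).  Backward pass yields the smoothed marginal distribution
    of the position at every hour.
    """
    alphas, step, ll = _forward(L, kernel, prior)
    T = len(L.times)
    probs = np.empty_like(alphas)
    sea = L.grid.sea_mask
    beta = sea.astype(float)
    p = alphas[-1] * beta
    probs[-1] = p / p.sum()
    for t in range(T - 2, -1, -1):
        beta = step.back(L.values[t + 1] * beta)
        s = beta.sum()
        if s == 0.0:
            raise InfeasibleTrackError(f"zero backward message at hour index {t}")
        beta = beta / s
        p = alphas[t] * beta
        probs[t] = p / p.sum()
    return PosteriorStack(grid=L.grid, times=L.times, probs=probs), ll


def estimate_sigma(L: LikelihoodStack, bounds: tuple[float, float] = (0.05, 5.0),
                   prior: np.ndarray | None = None, xatol: float = 1e-3,
                   ) -> SigmaEstimate:
    """Maximum-marginal-likelihood diffusion coefficient (cell units per
    sqrt-hour) by bounded scalar search.

    A flat or monotone likelihood profile (no movement information in the
    data) triggers a warning and returns the boundary value.
    """
    lo, hi = bounds
    profile: list[tuple[float, float]] = []

    def nll(s: float) -> float:
        # a sigma too small to bridge consecutive constraints is not an
        # error during the search, just an (effectively) -inf likelihood
        try:
            ll = forward_loglik(L, movement_kernel(s), prior)
        except InfeasibleTrackError:
            ll = -1e12 * (1.0 + (hi - s) / max(hi, 1.0))
        profile.append((float(s), ll))
        return -ll

    probe = [nll(lo), nll(0.5 * (lo + hi)), nll(hi)]
    if probe[2] >= 1e11:
        raise InfeasibleTrackError(
            "track infeasible for every sigma in the search bounds")
    if max(probe) - min(probe) < 1e-9:
        warnings.warn("likelihood profile is flat in sigma; returning the "
                      "lower bound", stacklevel=2)
        return SigmaEstimate(lo, -probe[0], _profile_df(profile), at_boundary=True)
    res = minimize_scalar(nll, bounds=bounds, method="bounded",
                          options={"xatol": xatol})
    sigma_hat = float(res.x)
    at_boundary = (sigma_hat - lo < 2 * xatol) or (hi - sigma_hat < 2 * xatol)
    if at_boundary:
        warnings.warn(f"sigma estimate {sigma_hat:.3f} is at the search "
                      f"boundary {bounds}", stacklevel=2)
    return SigmaEstimate(sigma_hat, -float(res.fun), _profile_df(profile),
                         at_boundary=at_boundary)


def _profile_df(profile: list[tuple[float, float]]) -> pd.DataFrame:
    df = pd.DataFrame(profile, columns=["sigma", "loglik"])
    return df.sort_values("sigma").reset_index(drop=True)


# ---------------------------------------------------------------------------
# track extraction and diagnostics
# ---------------------------------------------------------------------------

def extract_track(post: PosteriorStack) -> Track:
    """Posterior mean (probability-weighted centroid of sea-cell centres)
    and mode (argmax cell; ties break to the lowest (lat, lon) index) per
    hour, with the RMS distance from the mean in km."""
    grid = post.grid
    lon2d, lat2d = np.meshgrid(grid.lon, grid.lat)
    T = len(post.times)
    lon_mean = np.empty(T)
    lat_mean = np.empty(T)
    lon_mode = np.empty(T)
    lat_mode = np.empty(T)
    sd_km = np.empty(T)
    for t in range(T):
        p = post.probs[t]
        lon_mean[t] = float((p * lon2d).sum())
        lat_mean[t] = float((p * lat2d).sum())
        iy, ix = np.unravel_index(int(np.argmax(p)), p.shape)
        lon_mode[t] = grid.lon[ix]
        lat_mode[t] = grid.lat[iy]
        d2 = haversine_km(lon2d, lat2d, lon_mean[t], lat_mean[t]) ** 2
        sd_km[t] = float(np.sqrt((p * d2).sum()))
    return Track(data=pd.DataFrame({
        "time": post.times, "lon_mean": lon_mean, "lat_mean": lat_mean,
        "lon_mode": lon_mode, "lat_mode": lat_mode, "sd_km": sd_km}))


def daily_mean_track(track: Track) -> pd.DataFrame:
    """Mean of the hourly mean positions per calendar day."""
    df = track.data.copy()
    df["date"] = pd.DatetimeIndex(df["time"]).floor("D")
    g = df.groupby("date", sort=True)
    return pd.DataFrame({"date": list(g.groups.keys()),
                         "lon": g["lon_mean"].mean().values,
                         "lat": g["lat_mean"].mean().values})


def track_distance(track: Track, resolution: str = "daily") -> float:
    """Total distance travelled (km) along the mean track, summed at daily
    (default; hourly jitter inflates totals) or hourly resolution."""
    if resolution == "daily":
        df = daily_mean_track(track)
        lon, lat = df["lon"].values, df["lat"].values
    elif resolution == "hourly":
        lon = track.data["lon_mean"].values
        lat = track.data["lat_mean"].values
    else:
        raise ValueError("resolution must be 'hourly' or 'daily'")
    if len(lon) < 2:
        return 0.0
    return float(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]).sum())


def track_sensitivity(track_with: Track, track_without: Track,
                      ) -> tuple[float, float, float]:
    """Per-hour distance between the mean tracks estimated with and
    without acoustic detections; returns (mean, min, max) km."""
    a, b = track_with.data, track_without.data
    if len(a) != len(b) or not (a["time"].values == b["time"].values).all():
        raise ValueError("tracks have mismatched time axes")
    d = haversine_km(a["lon_mean"].values, a["lat_mean"].values,
                     b["lon_mean"].values, b["lat_mean"].values)
    return float(d.mean()), float(d.min()), float(d.max())
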