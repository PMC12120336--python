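"""Quality control of acoustic detections.

False detections arise from signal collisions and background noise.  Each
detection is scored against six criteria and given a verdict:

hard flags (always invalid)
    ``pre_release``          detection before the fish was released
    ``outside_deployment``   detection outside the receiver's deployment
                             interval, or at an unknown receiver

soft flags (1 = suspect but retained, >= 2 = invalid)
    ``isolated``             no same-tag detection within +/- the isolation
                             window at any station
    ``excess_velocity``      implied speed to the nearest-in-time same-tag
                             detection exceeds vmax
    ``implausible_release_distance``
                             farther from the release point than the fish
                             could have swum at vmax since release
    ``low_snr``              reported signal-to-noise ratio below snr_min
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .grid import haversine_km

log = logging.getLogger(__name__)

HARD_FLAGS = ["pre_release", "outside_deployment"]
SOFT_FLAGS = ["isolated", "excess_velocity", "implausible_release_distance", "low_snr"]
FLAGS = HARD_FLAGS + SOFT_FLAGS


def score_detections(dets: pd.DataFrame, receivers: pd.DataFrame,
                     fish: pd.DataFrame, cfg: AnalysisConfig | None = None,
                     ) -> pd.DataFrame:
    """Score every detection; returns one row per detection, aligned to
    ``dets`` by position, with the six boolean flags and a verdict in
    {valid, suspect, invalid}.

    Raises ``KeyError`` for a tag id absent from the fish metadata; an
    unknown receiver id is flagged ``outside_deployment`` and logged.
    """
    cfg = cfg or AnalysisConfig()
    n = len(dets)
    out = pd.DataFrame({f: np.zeros(n, dtype=bool) for f in FLAGS}, index=dets.index)

    release = fish.set_index("acoustic_tag_id")[
        ["release_time", "release_lon", "release_lat"]]
    unknown_tags = set(dets["tag_id"]) - set(release.index)
    if unknown_tags:
        raise KeyError(f"detections reference unknown tag id(s): {sorted(unknown_tags)}")

    recv = receivers.set_index("receiver_id")[["start", "end"]]
    unknown_recv = dets.loc[~dets["receiver_id"].isin(recv.index), "receiver_id"]
    if len(unknown_recv):
        log.warning("detections at unknown receiver(s) %s flagged outside_deployment",
                    sorted(set(unknown_recv)))

    # deployment check (vectorised over the whole table)
    joined = dets.join(recv, on="receiver_id")
    out["outside_deployment"] = (joined["start"].isna()
                                 | (dets["timestamp"] < joined["start"])
                                 | (dets["timestamp"] > joined["end"]))

    rel_t = release["release_time"].reindex(dets["tag_id"]).values
    out["pre_release"] = dets["timestamp"].values < rel_t

    # release-distance plausibility
    rel_lon = release["release_lon"].reindex(dets["tag_id"]).values
    rel_lat = release["release_lat"].reindex(dets["tag_id"]).values
    d_rel_km = haversine_km(dets["lon"].values, dets["lat"].values, rel_lon, rel_lat)
    elapsed_s = (dets["timestamp"].values - rel_t) / np.timedelta64(1, "s")
    reach_km = cfg.vmax * np.maximum(elapsed_s, 0.0) / 1000.0
    out["implausible_release_distance"] = d_rel_km > reach_km

    out["low_snr"] = dets["snr"].notna().values & (dets["snr"].values < cfg.snr_min)

    # per-tag temporal criteria (isolation, velocity), in timestamp order
    iso_s = cfg.isolation_window_h * 3600.0
    for _, g in dets.groupby("tag_id", sort=False):
        g = g.sort_values("timestamp", kind="mergesort")
        idx = g.index
        t = g["timestamp"].values.astype("datetime64[s]").astype(np.int64).astype(float)
        if len(g) == 1:
            out.loc[idx, "isolated"] = True
            continue
        gap_prev = np.r_[np.inf, np.diff(t)]
        gap_next = np.r_[np.diff(t), np.inf]
        out.loc[idx, "isolated"] = np.minimum(gap_prev, gap_next) > iso_s

        lon, lat = g["lon"].values, g["lat"].values
        st = g["station"].values
        d_prev = np.r_[np.nan, haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])]
        d_next = np.r_[d_prev[1:], np.nan]
        same_prev = np.r_[False, st[:-1] == st[1:]]
        same_next = np.r_[same_prev[1:], False]
        d_prev[same_prev] = 0.0
        d_next[same_next] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            v_prev = d_prev * 1000.0 / gap_prev
            v_next = d_next * 1000.0 / gap_next
            # zero distance in zero time is a repeat ping, not a speed
            v_prev[(d_prev == 0)] = 0.0
            v_next[(d_next == 0)] = 0.0
        use_prev = gap_prev <= gap_next
        v_nearest = np.where(use_prev, v_prev, v_next)
        v_nearest = np.where(np.isnan(v_nearest),
                             np.where(use_prev, v_next, v_prev), v_nearest)
        out.loc[idx, "excess_velocity"] = v_nearest > cfg.vmax

    hard = out[HARD_FLAGS].any(axis=1)
    n_soft = out[SOFT_FLAGS].sum(axis=1)
    out["verdict"] = np.select(
        [hard | (n_soft >= 2), n_soft == 1], ["invalid", "suspect"], default="valid")
    return out


def filter_detections(dets: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Drop detections whose verdict is invalid; order and index positions
    of the retained rows are preserved."""
    if len(scores) != len(dets):
        raise ValueError("scores not aligned to detections")
    keep = (scores["verdict"] != "invalid").values
    return dets.loc[keep].copy()


def qc_filter(dets: pd.DataFrame, receivers: pd.DataFrame, fish: pd.DataFrame,
              cfg: AnalysisConfig | None = None, max_passes: int = 10,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score-and-drop to a fixed point.

    Removing an invalid detection can change the neighbourhood-based flags
    (isolation, velocity) of the survivors, so scoring is repeated on the
    filtered table until no further row is dropped.  Returns the filtered
    table and the first-pass scores (one row per input detection).
    """
    first_scores = score_detections(dets, receivers, fish, cfg)
    current = filter_detections(dets, first_scores)
    for _ in range(max_passes):
        scores = score_detections(current, receivers, fish, cfg)
        nxt = filter_detections(current, scores)
        if len(nxt) == len(current):
            break
        current = nxt
    return current, first_scores
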