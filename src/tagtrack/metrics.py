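"""Survival proxies, residency periods, listening effort and movement graphs
derived from filtered acoustic detections.

Acoustic detections and recaptures serve as proxies of post-tagging
survival: short-term survival uses a pair of temporary receivers near the
release site (a fish sequentially detected at the inner and then the outer
station left the bay alive); long-term survival requires detection by the
permanent network or recapture at least a week after release.  Residency
periods are maximal runs of same-station detections separated by less than
a threshold gap.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

SEASONS = {12: "Winter", 1: "Winter", 2: "Winter",
           3: "Spring", 4: "Spring", 5: "Spring",
           6: "Summer", 7: "Summer", 8: "Summer",
           9: "Fall", 10: "Fall", 11: "Fall"}


def season_of(ts) -> str:
    """Meteorological season of a timestamp (Winter = DJF, etc.)."""
    return SEASONS[pd.Timestamp(ts).month]


def percent(k: int, n: int) -> int:
    """Percentage rounded half-up to an integer (reporting convention)."""
    return int(math.floor(100.0 * k / n + 0.5))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def flag_stationary_mortality(dets: pd.DataFrame, ping_interval_s: float = 180.0,
                              min_days: float = 7.0) -> pd.DataFrame:
    """Flag tags whose terminal detection run looks like a dead fish (or a
    shed tag) lying within range of a single receiver.

    A tag is flagged when its final run of detections is at one station
    with a median inter-detection gap of at most twice the nominal ping
    interval, sustained for at least ``min_days`` through the end of its
    series.  Returns one row per tag: ``flagged``, the station, and the
    start/end of the terminal run (to exclude from residency analysis).
    """
    rows = []
    for tag, g in dets.groupby("tag_id", sort=True):
        g = g.sort_values("timestamp", kind="mergesort")
        st = g["station"].values
        # maximal suffix at a single station
        i0 = len(st) - 1
        while i0 > 0 and st[i0 - 1] == st[-1]:
            i0 -= 1
        run = g.iloc[i0:]
        span_days = (run["timestamp"].iloc[-1] - run["timestamp"].iloc[0]
                     ).total_seconds() / 86400.0
        med_gap = (run["timestamp"].diff().dt.total_seconds().median()
                   if len(run) > 1 else float("inf"))
        flagged = (span_days >= min_days) and (med_gap <= 2.0 * ping_interval_s)
        rows.append({"tag_id": tag, "flagged": flagged, "station": st[-1],
                     "start": run["timestamp"].iloc[0],
                     "end": run["timestamp"].iloc[-1],
                     "median_gap_s": med_gap, "span_days": span_days,
                     "n_detections": len(run)})
    return pd.DataFrame(rows)


def drop_mortality_runs(dets: pd.DataFrame, mortality: pd.DataFrame) -> pd.DataFrame:
    """Remove the terminal stationary runs of flagged tags from a
    detection table (they reflect a carcass, not residency behaviour)."""
    if mortality.empty:
        return dets
    keep = np.ones(len(dets), dtype=bool)
    for _, m in mortality[mortality["flagged"]].iterrows():
        keep &= ~((dets["tag_id"].values == m["tag_id"])
                  & (dets["station"].values == m["station"])
                  & (dets["timestamp"].values >= np.datetime64(m["start"])))
    return dets.loc[keep].copy()


def classify_short_term(dets: pd.DataFrame, fish: pd.DataFrame,
                        station_a: str, station_b: str,
                        assessable: pd.Series | None = None) -> pd.DataFrame:
    """Short-term survival from a sequential two-temporary-station design.

    ``station_a`` is nearest the release point and ``station_b`` on the way
    out of the monitored bay.  A fish is a survivor if detected at A and
    subsequently at B, or if detected anywhere else in the network (it
    escaped the bay unseen); presumed dead if its only record is a
    continuous stationary run at a single temporary station; otherwise
    unassessed.  ``assessable`` restricts scoring to fish actually released
    inside the monitored bay.
    """
    mort = flag_stationary_mortality(dets)
    mort = mort.set_index("tag_id") if len(mort) else mort
    rows = []
    for i, f in fish.iterrows():
        tag = f["acoustic_tag_id"]
        if assessable is not None and not bool(assessable.loc[i]):
            rows.append({"tag_id": tag, "short_term": "unassessed", "evidence": []})
            continue
        g = dets[dets["tag_id"] == tag].sort_values("timestamp")
        evidence: list[str] = []
        verdict = "unassessed"
        at_a = g[g["station"] == station_a]["timestamp"]
        at_b = g[g["station"] == station_b]["timestamp"]
        elsewhere = g[~g["station"].isin([station_a, station_b])]
        if len(at_a) and len(at_b) and at_b.max() > at_a.min():
            verdict = "survivor"
            evidence.append(f"sequential {station_a}->{station_b}")
        if len(elsewhere):
            verdict = "survivor"
            evidence.append("detected outside the bay")
        if verdict == "unassessed" and tag in getattr(mort, "index", []):
            m = mort.loc[tag]
            if m["flagged"] and m["station"] in (station_a, station_b):
                verdict = "presumed_dead"
                evidence.append(f"continuous detections at {m['station']}")
        rows.append({"tag_id": tag, "short_term": verdict, "evidence": evidence})
    return pd.DataFrame(rows)


def classify_long_term(dets: pd.DataFrame, fish: pd.DataFrame,
                       survival_week_days: float = 7.0,
                       exclude_stations: Iterable[str] = ()) -> pd.DataFrame:
    """Long-term survival proxy: detected by the permanent network (the
    temporary stations are excluded) and/or recaptured at least
    ``survival_week_days`` days after release; otherwise unknown."""
    excl = set(exclude_stations)
    week = pd.Timedelta(days=survival_week_days)
    rows = []
    for _, f in fish.iterrows():
        tag = f["acoustic_tag_id"]
        cut = f["release_time"] + week
        g = dets[(dets["tag_id"] == tag) & ~dets["station"].isin(excl)]
        detected_late = bool((g["timestamp"] >= cut).any())
        recaptured_late = (pd.notna(f.get("recapture_time"))
                           and f["recapture_time"] >= cut)
        evidence = []
        if detected_late:
            evidence.append("network detection after a week at sea")
        if recaptured_late:
            evidence.append("recaptured after a week at sea")
        rows.append({"tag_id": tag,
                     "long_term": "survivor" if evidence else "unknown",
                     "evidence": evidence})
    return pd.DataFrame(rows)


def survival_rates(records: pd.DataFrame, column: str = "long_term",
                   survivor_value: str = "survivor",
                   cohorts: Mapping[str, pd.Series] | None = None) -> dict:
    """Survival percentages (rounded half-up) for the whole cohort and any
    named sub-cohorts (boolean masks aligned to ``records``).  Empty
    cohorts are reported as absent."""
    # duplicated tag ids (e.g. duplicated detections upstream) never
    # inflate a cohort: one record per tag
    records = records.drop_duplicates(subset="tag_id")
    masks: dict[str, pd.Series] = {"all": pd.Series(True, index=records.index)}
    if cohorts:
        for name, m in cohorts.items():
            masks[name] = m.reindex(records.index, fill_value=False)
    out = {}
    for name, m in masks.items():
        sub = records.loc[m.astype(bool)]
        n = len(sub)
        if n == 0:
            continue
        k = int((sub[column] == survivor_value).sum())
        out[name] = {"survivors": k, "n": n, "rate_pct": percent(k, n)}
    return out


# ---------------------------------------------------------------------------
# residency
# ---------------------------------------------------------------------------

def compute_residency_periods(dets: pd.DataFrame, threshold_h: float = 24.0,
                              exclude_stations: Iterable[str] = (),
                              ) -> pd.DataFrame:
    """Split each (tag, station) detection sequence into residency periods.

    Consecutive detections closer than ``threshold_h`` hours belong to the
    same period; a gap of at least the threshold starts a new one.  A
    single detection forms a period of duration 0.
    """
    excl = set(exclude_stations)
    d = dets[~dets["station"].isin(excl)]
    thr = pd.Timedelta(hours=threshold_h)
    rows = []
    for (tag, st), g in d.groupby(["tag_id", "station"], sort=True):
        t = g["timestamp"].sort_values(kind="mergesort").reset_index(drop=True)
        new = t.diff() >= thr
        period_id = new.cumsum()
        for _, p in t.groupby(period_id):
            rows.append({"tag_id": tag, "station": st,
                         "start": p.iloc[0], "end": p.iloc[-1],
                         "n_detections": len(p),
                         "duration_h": (p.iloc[-1] - p.iloc[0]).total_seconds() / 3600.0})
    return pd.DataFrame(rows, columns=["tag_id", "station", "start", "end",
                                       "n_detections", "duration_h"])


def residency_summary(periods: pd.DataFrame, fish: pd.DataFrame | None = None,
                      ) -> pd.DataFrame:
    """Per-fish number of residency periods and mean duration; joined with
    length and maturity when fish metadata is given."""
    if periods.empty:
        return pd.DataFrame(columns=["tag_id", "n_periods", "mean_duration_h"])
    g = periods.groupby("tag_id")
    out = pd.DataFrame({"n_periods": g.size(),
                        "mean_duration_h": g["duration_h"].mean()}).reset_index()
    if fish is not None:
        meta = fish.set_index("acoustic_tag_id")[["total_length_mm", "maturity"]]
        out = out.join(meta, on="tag_id")
    return out


def residency_sensitivity(dets: pd.DataFrame,
                          thresholds_h: Sequence[float] = tuple(range(1, 25)),
                          exclude_stations: Iterable[str] = ()) -> pd.DataFrame:
    """Number of residency periods per fish for a sweep of gap thresholds
    (non-increasing in the threshold, by construction)."""
    rows = []
    for thr in thresholds_h:
        periods = compute_residency_periods(dets, thr, exclude_stations)
        if periods.empty:
            continue
        for tag, g in periods.groupby("tag_id"):
            rows.append({"threshold_h": thr, "tag_id": tag,
                         "n_periods": len(g),
                         "mean_duration_h": g["duration_h"].mean()})
    return pd.DataFrame(rows, columns=["threshold_h", "tag_id", "n_periods",
                                       "mean_duration_h"])


# ---------------------------------------------------------------------------
# listening effort
# ---------------------------------------------------------------------------

def listening_effort(receivers: pd.DataFrame) -> pd.DataFrame:
    """Cumulative listening days per calendar month across all receivers.

    A receiver contributes the (fractional) number of days its deployment
    interval overlaps each month; contributions are summed over receivers.
    """
    start = receivers["start"].min()
    end = receivers["end"].max()
    months = pd.period_range(start.to_period("M"), end.to_period("M"), freq="M")
    days = np.zeros(len(months))
    for _, r in receivers.iterrows():
        for i, m in enumerate(months):
            lo = max(r["start"], m.start_time)
            hi = min(r["end"], (m + 1).start_time)
            if hi > lo:
                days[i] += (hi - lo).total_seconds() / 86400.0
    return pd.DataFrame({"month": months, "listening_days": days})


def detections_per_listening_day(dets: pd.DataFrame, effort: pd.DataFrame,
                                 fish: pd.DataFrame | None = None) -> pd.DataFrame:
    """Monthly detection and distinct-individual counts normalised by
    listening effort, overall and (when fish metadata is given) by
    maturity class."""
    effort = effort.set_index("month")
    d = dets.copy()
    d["month"] = d["timestamp"].dt.to_period("M")
    classes = {"all": pd.Series(True, index=d.index)}
    if fish is not None:
        mat = fish.set_index("acoustic_tag_id")["maturity"]
        fish_class = mat.reindex(d["tag_id"]).values
        for cls in ("immature", "mature"):
            classes[cls] = pd.Series(fish_class == cls, index=d.index)
    rows = []
    for cls, mask in classes.items():
        sub = d.loc[mask]
        for month, g in sub.groupby("month"):
            ld = float(effort["listening_days"].get(month, np.nan))
            rows.append({"month": month, "length_class": cls,
                         "n_detections": len(g),
                         "n_individuals": g["tag_id"].nunique(),
                         "listening_days": ld,
                         "det_per_day": len(g) / ld if ld > 0 else np.nan,
                         "ind_per_day": g["tag_id"].nunique() / ld if ld > 0 else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# movement graphs
# ---------------------------------------------------------------------------

def _event_sequence(tag: str, f: pd.Series, dets: pd.DataFrame) -> list[tuple]:
    events = [(f["release_time"], f.get("release_site") or
               f"release({f['release_lon']:.3f},{f['release_lat']:.3f})")]
    g = dets[dets["tag_id"] == tag].sort_values("timestamp")
    events += list(zip(g["timestamp"], g["station"]))
    if pd.notna(f.get("recapture_time")):
        site = f.get("recapture_site") or \
            f"recapture({f['recapture_lon']:.3f},{f['recapture_lat']:.3f})"
        events.append((f["recapture_time"], site))
    # collapse consecutive repeats of the same site
    seq = []
    for t, site in events:
        if not seq or seq[-1][1] != site:
            seq.append((t, site))
    return seq


def build_movement_graph(dets: pd.DataFrame, fish: pd.DataFrame) -> nx.MultiDiGraph:
    """Directed seasonal movement graph between stations and release /
    recapture sites.

    For each fish the ordered sequence of located events (release,
    station-level detections, recapture) yields one directed edge per pair
    of consecutive distinct locations, attributed to the season of the
    later event and the fish's maturity class.  Parallel edges are merged
    per (season, maturity); ``n_fish`` counts distinct individuals.
    """
    G = nx.MultiDiGraph()
    for _, f in fish.iterrows():
        tag = f["acoustic_tag_id"]
        seq = _event_sequence(tag, f, dets)
        for (t0, a), (t1, b) in zip(seq[:-1], seq[1:]):
            season = season_of(t1)
            key = (season, f["maturity"])
            if G.has_edge(a, b, key=key):
                data = G.edges[a, b, key]
                if tag not in data["fish_ids"]:
                    data["fish_ids"].append(tag)
                    data["n_fish"] += 1
            else:
                G.add_edge(a, b, key=key, season=season, maturity=f["maturity"],
                           n_fish=1, fish_ids=[tag])
    return G


def graph_edge_table(G: nx.MultiDiGraph) -> pd.DataFrame:
    rows = [{"from": a, "to": b, "season": d["season"], "maturity": d["maturity"],
             "n_fish": d["n_fish"]} for a, b, d in G.edges(data=True)]
    return pd.DataFrame(rows, columns=["from", "to", "season", "maturity", "n_fish"])
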