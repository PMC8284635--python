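"""GPS trip integration: speeds, filters, behaviour-fix assignment, trips,
daily activity budgets.

Detected behaviours live on the tag clock (seconds from acceleration start);
GPS fixes carry absolute timestamps.  Functions that join the two take the
record start time ``t0`` to convert.  Behaviours aggregate into three
functional categories: foraging (surface seizing + foraging dives), transit
(flight + take-offs), and rest; everything else is unknown.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Ethogram, GpsTrack

#: WGS84 mean Earth radius, km.
_EARTH_RADIUS_KM = 6371.0088

CATEGORY_OF = {
    "surface_seizing": "forage",
    "foraging_dive": "forage",
    "flight": "transit",
    "take_off": "transit",
    "rest": "rest",
    "unknown": "unknown",
}


@dataclass
class Trip:
    """A continuous excursion outside the colony radius."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration_days: int        # ceiling of elapsed days
    category: str             # "long" (>2 days) or "short" (<=2 days)
    fixes: pd.DataFrame


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (haversine, WGS84 mean radius); vectorised."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def compute_speeds(track: GpsTrack, window_fixes: int = 5) -> GpsTrack:
    """Smoothed travel speed per fix from a moving window of positions.

    The speed at fix *i* is the great-circle distance between the first and
    last fix of the centred ``window_fixes`` window divided by the window's
    time span; windows shrink at the track edges.  Using window endpoints
    rather than consecutive fixes suppresses GPS position jitter.
    """
    df = track.df.copy()
    n = len(df)
    if n < 2:
        raise ValueError("need at least two fixes to compute speed")
    half = window_fixes // 2
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
    tsec = df["time"].astype("int64").to_numpy() / 1e9
    i = np.arange(n)
    j0 = np.maximum(0, i - half)
    j1 = np.minimum(n - 1, i + half)
    # degenerate at ends: ensure a span of at least one fix pair
    j1 = np.where(j1 == j0, np.minimum(n - 1, j0 + 1), j1)
    j0 = np.where(j1 == j0, np.maximum(0, j1 - 1), j0)
    dist = great_circle_km(lat[j0], lon[j0], lat[j1], lon[j1])
    dt_h = (tsec[j1] - tsec[j0]) / 3600.0
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(dt_h > 0, dist / dt_h, 0.0)
    df["speed_kph"] = speed
    return GpsTrack(df)


def filter_fixes(
    track: GpsTrack,
    colony: tuple[float, float],
    radius_km: float = 1.5,
    max_speed_kph: float = 80.0,
) -> GpsTrack:
    """Drop fixes within the colony radius or moving unrealistically fast."""
    df = track.df
    d = great_circle_km(df["lat"].to_numpy(), df["lon"].to_numpy(),
                        colony[0], colony[1])
    keep = (d >= radius_km) & ~(df["speed_kph"].to_numpy() > max_speed_kph)
    if not keep.any():
        warnings.warn("all fixes removed by colony/speed filters", stacklevel=2)
    return GpsTrack(df.loc[keep].reset_index(drop=True))


def assign_behaviour(
    track: GpsTrack,
    ethogram: Ethogram,
    t0: pd.Timestamp,
    window_s: float = 30.0,
) -> GpsTrack:
    """Label fixes with foraging behaviours detected within ``window_s``.

    A fix takes ``foraging_dive`` if any dive interval lies within the
    window, else ``surface_seizing`` if a seizing interval does (dives win
    ties); otherwise the behaviour stays unset.
    """
    df = track.df.copy()
    tsec = (df["time"] - pd.Timestamp(t0)).dt.total_seconds().to_numpy()

    def near(label: str) -> np.ndarray:
        hit = np.zeros(len(df), dtype=bool)
        for s, e in ethogram.select(label):
            gap = np.maximum(s - tsec, tsec - e)
            hit |= gap <= window_s
        return hit

    beh = np.array([None] * len(df), dtype=object)
    beh[near("surface_seizing")] = "surface_seizing"
    beh[near("foraging_dive")] = "foraging_dive"
    df["behaviour"] = beh
    return GpsTrack(df)


def reclassify_fast_foraging(
    track: GpsTrack, max_forage_speed_kph: float = 15.0
) -> GpsTrack:
    """Relabel foraging fixes moving strictly faster than the ceiling as flight."""
    df = track.df.copy()
    is_forage = df["behaviour"].isin(["surface_seizing", "foraging_dive"])
    fast = df["speed_kph"] > max_forage_speed_kph
    df.loc[is_forage & fast, "behaviour"] = "flight"
    return GpsTrack(df)


def prune_short_behaviours(ethogram: Ethogram, min_s: float = 5.0) -> Ethogram:
    """Delete flight and unknown intervals lasting strictly less than ``min_s``.

    Removed intervals become unlabelled gaps (read back as unknown when the
    ethogram is sampled).
    """
    kept = [
        (s, e, l)
        for s, e, l in ethogram.intervals
        if not (l in ("flight", "unknown") and (e - s) < min_s)
    ]
    return Ethogram(kept)


def segment_trips(
    track: GpsTrack, colony: tuple[float, float], radius_km: float = 1.5
) -> list[Trip]:
    """Split the track into foraging trips: runs of fixes outside the colony.

    Trip duration is the ceiling of elapsed time in whole days; trips longer
    than two days are "long", the rest "short".
    """
    df = track.df
    d = great_circle_km(df["lat"].to_numpy(), df["lon"].to_numpy(),
                        colony[0], colony[1])
    away = d >= radius_km
    trips: list[Trip] = []
    edges = np.flatnonzero(np.diff(away.astype(int)))
    bounds = np.concatenate(([0], edges + 1, [len(df)]))
    for a, b in zip(bounds, bounds[1:]):
        if not away[a]:
            continue
        sub = df.iloc[a:b]
        start, end = sub["time"].iloc[0], sub["time"].iloc[-1]
        elapsed_days = (end - start).total_seconds() / 86400.0
        days = max(1, math.ceil(elapsed_days))
        trips.append(
            Trip(
                start=start,
                end=end,
                duration_days=days,
                category="long" if days > 2 else "short",
                fixes=sub.reset_index(drop=True),
            )
        )
    return trips


def daily_budget(
    ethogram: Ethogram,
    t0: pd.Timestamp,
    tz_offset_hours: float = 9.0,
) -> pd.DataFrame:
    """Per-calendar-day activity budget from a classified ethogram.

    Days are bounded by local midnight (``tz_offset_hours`` east of UTC,
    default UTC+9 for the study region).  Per day, seconds and fractions in
    forage / transit / rest / unknown (fractions of the labelled duration in
    that day, summing to 1) plus counts of surface-seizing events and dives,
    counted on the day containing the event start.
    """
    t0 = pd.Timestamp(t0)
    local0 = t0 + pd.Timedelta(hours=tz_offset_hours)
    day0 = local0.normalize()
    offset_s = (local0 - day0).total_seconds()  # seconds into the first local day

    rows: dict[pd.Timestamp, dict[str, float]] = {}

    def day_of(sec: float) -> pd.Timestamp:
        return day0 + pd.Timedelta(days=math.floor((sec + offset_s) / 86400.0))

    for s, e, lab in ethogram.intervals:
        cat = CATEGORY_OF[lab]
        cur = s
        while cur < e:
            day = day_of(cur)
            day_end_sec = (day + pd.Timedelta(days=1) - day0).total_seconds() - offset_s
            chunk_end = min(e, day_end_sec)
            row = rows.setdefault(
                day, {"forage_s": 0.0, "transit_s": 0.0, "rest_s": 0.0,
                      "unknown_s": 0.0, "n_surface_seizing": 0, "n_dives": 0}
            )
            row[f"{cat}_s"] += chunk_end - cur
            cur = chunk_end
        start_day = day_of(s)
        if lab == "surface_seizing":
            rows[start_day]["n_surface_seizing"] += 1
        elif lab == "foraging_dive":
            rows[start_day]["n_dives"] += 1

    records = []
    for day in sorted(rows):
        row = rows[day]
        total = sum(row[f"{c}_s"] for c in ("forage", "transit", "rest", "unknown"))
        rec = {"day": day, **row, "total_s": total}
        for c in ("forage", "transit", "rest", "unknown"):
            rec[f"{c}_frac"] = row[f"{c}_s"] / total if total > 0 else math.nan
        records.append(rec)
    return pd.DataFrame(records)
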