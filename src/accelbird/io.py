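"""Tag-data input/output: acceleration exports, ethogram intervals, GPS fixes.

All times inside the package are seconds from the start of the acceleration
record, with intervals half-open ``[start, end)``.  Absolute UTC time is kept
only as ``t0`` metadata on the containers.  Acceleration is always in g.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Closed behaviour vocabulary used throughout the package.
LABELS = ("flight", "take_off", "surface_seizing", "foraging_dive", "rest", "unknown")


class TagKind(str, enum.Enum):
    """Mounting position of the tag; mounting alters the signal conventions."""

    chest_mounted = "chest_mounted"   # video + acceleration logger on the chest
    back_mounted = "back_mounted"     # GPS + acceleration logger on the back


class SchemaError(ValueError):
    """Required column missing or unmappable in a delimited export."""


class GapError(ValueError):
    """Non-uniform sampling beyond tolerance; carries the gap positions."""

    def __init__(self, message: str, gap_indices: Sequence[int]):
        super().__init__(message)
        self.gap_indices = list(gap_indices)


class EthogramError(ValueError):
    """Overlapping, inverted or otherwise invalid behaviour intervals."""


class VocabularyError(ValueError):
    """Behaviour label outside the closed vocabulary."""


@dataclass
class AccelSeries:
    """Uniformly sampled tri-axial acceleration in g.

    Axes follow the tag convention: ``x`` longitudinal, ``y`` lateral,
    ``z`` dorsoventral.
    """

    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    t0: pd.Timestamp | None = None
    tag_kind: TagKind = TagKind.chest_mounted

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if len(self.x) < 1:
            raise ValueError("empty acceleration series")
        if isinstance(self.tag_kind, str):
            self.tag_kind = TagKind(self.tag_kind)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample instants in seconds from record start."""
        return np.arange(self.n) / self.fs


@dataclass
class Ethogram:
    """Ordered, non-overlapping labelled behaviour intervals.

    ``intervals`` is a list of ``(start_s, end_s, label)`` with half-open
    ``[start, end)`` semantics on the tag clock.  Gaps are permitted (they
    read back as ``unknown`` when sampled).
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(s), float(e), str(l)) for s, e, l in self.intervals]
        ivs.sort(key=lambda iv: (iv[0], iv[1]))
        for s, e, l in ivs:
            if l not in LABELS:
                raise VocabularyError(f"unknown behaviour label {l!r}")
            if not e > s:
                raise EthogramError(f"interval end {e} must exceed start {s}")
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise EthogramError(
                    f"overlapping intervals: [{s0}, {e0}) and starting {s1}"
                )
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def end_s(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def total_duration(self, label: str | None = None) -> float:
        """Summed duration, optionally restricted to one behaviour."""
        return sum(e - s for s, e, l in self.intervals if label is None or l == label)

    def duration_by_label(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for s, e, l in self.intervals:
            out[l] = out.get(l, 0.0) + (e - s)
        return out

    def select(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, l in self.intervals if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s", "label"])


@dataclass
class GpsFix:
    """A single positional fix (WGS84 degrees)."""

    time: pd.Timestamp
    lat: float
    lon: float
    speed_kph: float | None = None
    behaviour: str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")


@dataclass
class GpsTrack:
    """Time-sorted GPS fixes with optional derived speed and behaviour columns."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time", "lat", "lon"}
        if not required.issubset(self.df.columns):
            raise SchemaError(f"GPS track needs columns {sorted(required)}")
        df = self.df.copy()
        df["time"] = pd.to_datetime(df["time"])
        if not df["time"].is_monotonic_increasing:
            df = df.sort_values("time", kind="stable")
        lat, lon = df["lat"].to_numpy(float), df["lon"].to_numpy(float)
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("GPS coordinates out of range")
        if "speed_kph" not in df.columns:
            df["speed_kph"] = np.nan
        if "behaviour" not in df.columns:
            df["behaviour"] = None
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def fixes(self) -> list[GpsFix]:
        return [
            GpsFix(row.time, row.lat, row.lon,
                   None if pd.isna(row.speed_kph) else float(row.speed_kph),
                   row.behaviour if isinstance(row.behaviour, str) else None)
            for row in self.df.itertuples()
        ]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_CANONICAL_ACCEL_COLS = ("time", "x", "y", "z")


def read_accel(
    path,
    fs: float,
    tag_kind: TagKind | str = TagKind.chest_mounted,
    column_map: dict[str, str] | None = None,
    gap_policy: str = "reject",
    gap_tolerance: float = 0.5,
):
    """Read a delimited acceleration export into :class:`AccelSeries`.

    Parameters
    ----------
    fs
        Declared sampling rate in Hz; timestamps are verified uniform at
        this rate within ``gap_tolerance`` sample periods.
    column_map
        Maps canonical names (``time``/``index``, ``x``, ``y``, ``z``) to
        the file's column names, for vendor exports.
    gap_policy
        ``"reject"`` raises :class:`GapError` on any gap; ``"split"``
        returns a list of contiguous :class:`AccelSeries` segments.
    """
    if gap_policy not in ("reject", "split"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    df = pd.read_csv(path)
    cmap = dict(column_map or {})
    for canon in ("x", "y", "z"):
        col = cmap.get(canon, canon)
        if col not in df.columns:
            raise SchemaError(f"column for {canon!r} ({col!r}) not found in {list(df.columns)}")
    time_col = cmap.get("time", "time" if "time" in df.columns else None)
    index_col = cmap.get("index", "index" if "index" in df.columns else None)

    t0 = None
    gap_after: np.ndarray = np.array([], dtype=int)
    if time_col is not None:
        raw_t = df[time_col]
        if pd.api.types.is_numeric_dtype(raw_t):
            t = raw_t.to_numpy(float)
        else:
            ts = pd.to_datetime(raw_t)
            t0 = ts.iloc[0]
            t = (ts - t0).dt.total_seconds().to_numpy()
        dt = np.diff(t)
        bad = np.abs(dt - 1.0 / fs) > gap_tolerance / fs
        gap_after = np.flatnonzero(bad)
    elif index_col is not None:
        idx = df[index_col].to_numpy(float)
        gap_after = np.flatnonzero(np.diff(idx) != 1)
    # with neither a time nor index column samples are taken as contiguous

    def _make(sub: pd.DataFrame) -> AccelSeries:
        return AccelSeries(
            fs=fs,
            x=sub[cmap.get("x", "x")].to_numpy(float),
            y=sub[cmap.get("y", "y")].to_numpy(float),
            z=sub[cmap.get("z", "z")].to_numpy(float),
            t0=t0,
            tag_kind=tag_kind,
        )

    if len(gap_after) and gap_policy == "reject":
        raise GapError(
            f"{len(gap_after)} sampling gap(s) after row indices {list(gap_after[:10])}",
            gap_after,
        )
    if len(gap_after):
        bounds = [0, *(gap_after + 1), len(df)]
        return [_make(df.iloc[a:b]) for a, b in zip(bounds, bounds[1:]) if b > a]
    return _make(df)


def read_ethogram(path) -> Ethogram:
    """Read ``start_s,end_s,label`` CSV into a validated :class:`Ethogram`."""
    df = pd.read_csv(path)
    for col in ("start_s", "end_s", "label"):
        if col not in df.columns:
            raise SchemaError(f"ethogram file missing column {col!r}")
    return Ethogram(list(zip(df["start_s"], df["end_s"], df["label"])))


def write_ethogram(ethogram: Ethogram, path) -> None:
    ethogram.to_frame().to_csv(path, index=False)


def read_gps(path, dedup: str = "first") -> GpsTrack:
    """Read ``time,lat,lon`` CSV into a time-sorted :class:`GpsTrack`.

    ``dedup`` handles duplicated timestamps: ``"first"``/``"last"`` keep one
    fix per instant, ``"error"`` raises.
    """
    df = pd.read_csv(path)
    for col in ("time", "lat", "lon"):
        if col not in df.columns:
            raise SchemaError(f"GPS file missing column {col!r}")
    df["time"] = pd.to_datetime(df["time"])
    if df["time"].duplicated().any():
        if dedup == "error":
            raise ValueError("duplicated GPS timestamps")
        if dedup not in ("first", "last"):
            raise ValueError(f"unknown dedup policy {dedup!r}")
        df = df.drop_duplicates(subset="time", keep=dedup)
    return GpsTrack(df)


def write_gps(track: GpsTrack, path) -> None:
    track.df.to_csv(path, index=False)


def write_accel(series: AccelSeries, path) -> None:
    pd.DataFrame(
        {"time": series.times(), "x": series.x, "y": series.y, "z": series.z}
    ).to_csv(path, index=False)
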