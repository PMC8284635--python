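"""Rule-based behaviour classification from calibrated acceleration signals.

The classifier turns a calibrated tag record into an ethogram over six
labels: flight, take_off, surface_seizing, foraging_dive, rest, unknown.

Flaps are dorsoventral peak-trough pairs above the calibrated amplitude
threshold; they agglomerate into flapping bouts (gaps < 0.5 s) and then into
flight intervals (bout gaps <= 30 s), so enclosed glides count as flight.
Large pitch-change events drive everything else: an upward event at a flight
onset marks a take-off; events grouped within 23.3 s (the mean foraging bout
duration) are screened first for foraging dives (pitch dropping 30 deg below
the PFM minimum-pitch median, then recovering above the PFM mean + 2x
variance within 10 s) and then for surface seizing (3+ events within 2 s of
one another); groups matching neither stay unknown.  Rest is assigned where
the 10 s moving mean of ODBA stays below 0.2 g.  Overlaps resolve by
precedence dive > surface seizing > take-off > flight > rest > unknown.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationProfile
from .io import AccelSeries, Ethogram, TagKind
from .signal import (
    DecomposedSeries,
    OdbaSeries,
    PitchSeries,
    decompose,
    local_extrema,
    odba,
    pitch,
)


@dataclass
class ClassifierConfig:
    """Every constant of the detection rules, exposed for configuration."""

    cutoff_hz: float = 1.5
    filter_order: int = 100
    spectrogram_window_s: float = 4.0
    spectrogram_overlap: float = 0.85
    flap_band: tuple[float, float] = (3.5, 5.0)
    intra_bout_gap_s: float = 0.5
    inter_bout_gap_s: float = 30.0
    takeoff_search_window_s: float = 2.0
    event_group_window_s: float = 23.3
    dive_descent_margin_deg: float = 30.0
    dive_ascent_window_s: float = 10.0
    seize_burst_gap_s: float = 2.0
    seize_min_events: int = 3
    seize_all_pairs: bool = False
    rest_threshold_g: float = 0.2
    rest_window_s: float = 10.0


@dataclass
class FlapEvent:
    """One wingbeat: a peak-trough pair above the flap amplitude threshold."""

    peak_index: int
    trough_index: int
    amplitude_g: float

    @property
    def start_index(self) -> int:
        return min(self.peak_index, self.trough_index)

    @property
    def end_index(self) -> int:
        return max(self.peak_index, self.trough_index)


@dataclass
class PitchChangeEvent:
    """A successive pitch-extremum difference above the calibrated threshold."""

    time_s: float            # time of the first extremum of the pair
    end_time_s: float        # time of the second extremum
    magnitude_deg: float
    direction: str           # "up" or "down"
    origin_pitch_deg: float  # pitch at the first extremum


def detect_flaps(
    decomposed: DecomposedSeries, profile: CalibrationProfile
) -> list[FlapEvent]:
    """Dorsoventral extremum pairs at or above the flap threshold (>=)."""
    ext = local_extrema(decomposed.z_d)
    out: list[FlapEvent] = []
    for k in range(len(ext) - 1):
        amp = abs(ext.values[k + 1] - ext.values[k])
        if amp >= profile.flap_threshold_g:
            if ext.is_max[k]:
                pk, tr = ext.indices[k], ext.indices[k + 1]
            else:
                pk, tr = ext.indices[k + 1], ext.indices[k]
            out.append(FlapEvent(int(pk), int(tr), float(amp)))
    return out


def _agglomerate(
    spans: list[tuple[float, float]], max_gap: float, strict: bool
) -> list[tuple[float, float]]:
    """Merge time-sorted spans whose gap is < max_gap (strict) or <= max_gap."""
    merged: list[list[float]] = []
    for s, e in spans:
        if merged:
            gap = s - merged[-1][1]
            if (gap < max_gap) if strict else (gap <= max_gap):
                merged[-1][1] = max(merged[-1][1], e)
                continue
        merged.append([s, e])
    return [(a, b) for a, b in merged]


def group_flight(
    flaps: list[FlapEvent],
    fs: float,
    intra_bout_gap_s: float = 0.5,
    inter_bout_gap_s: float = 30.0,
) -> list[tuple[float, float]]:
    """Two-level agglomeration of flaps into flight intervals.

    Flaps closer than ``intra_bout_gap_s`` share a flapping bout; bouts no
    more than ``inter_bout_gap_s`` apart share a flight interval, so glides
    between bouts are included in flight.
    """
    spans = sorted(
        ((f.start_index / fs, f.end_index / fs) for f in flaps)
    )
    bouts = _agglomerate(spans, intra_bout_gap_s, strict=True)
    return _agglomerate(bouts, inter_bout_gap_s, strict=False)


def pitch_change_events(
    pitchseries: PitchSeries,
    profile: CalibrationProfile,
    apply_mount_filter: bool = True,
) -> list[PitchChangeEvent]:
    """Large pitch changes: successive extremum pairs >= the calibrated threshold.

    For back-mounted tags, upward events originating above the median of
    minimum PFM pitch are removed (in steady flight the pitch already sits
    near its median, so such events are wingbeat/wind artefacts rather than
    recoveries from a low-pitch landing or dive).
    """
    ext = local_extrema(pitchseries.pitch_deg)
    fs = pitchseries.fs
    events: list[PitchChangeEvent] = []
    for k in range(len(ext) - 1):
        mag = abs(ext.values[k + 1] - ext.values[k])
        if mag < profile.large_pitch_change_deg:
            continue
        up = ext.values[k + 1] > ext.values[k]
        ev = PitchChangeEvent(
            time_s=ext.indices[k] / fs,
            end_time_s=ext.indices[k + 1] / fs,
            magnitude_deg=float(mag),
            direction="up" if up else "down",
            origin_pitch_deg=float(ext.values[k]),
        )
        events.append(ev)
    if apply_mount_filter and profile.tag_kind is TagKind.back_mounted:
        events = [
            e
            for e in events
            if not (
                e.direction == "up"
                and e.origin_pitch_deg > profile.pfm_pitch_min_med_deg
            )
        ]
    return events


def detect_takeoffs(
    flight_intervals: list[tuple[float, float]],
    events: list[PitchChangeEvent],
    profile: CalibrationProfile,
    search_window_s: float = 2.0,
) -> list[tuple[float, float]]:
    """Take-offs: upward large pitch changes at flight-interval onsets.

    An upward event whose start lies within ``search_window_s`` of a flight
    onset marks a take-off spanning the pitch excursion.  For back-mounted
    tags upward events originating above the PFM minimum-pitch median are
    discarded first (idempotent if the events were already filtered).
    """
    ups = [e for e in events if e.direction == "up"]
    if profile.tag_kind is TagKind.back_mounted:
        ups = [e for e in ups if e.origin_pitch_deg <= profile.pfm_pitch_min_med_deg]
    out = []
    for s, _ in flight_intervals:
        near = [e for e in ups if abs(e.time_s - s) <= search_window_s]
        if near:
            e = min(near, key=lambda ev: abs(ev.time_s - s))
            out.append((e.time_s, max(e.end_time_s, e.time_s + 1.0 / 1e9)))
    # merge duplicates if two onsets matched the same event
    return _agglomerate(sorted(set(out)), 0.0, strict=False)


def group_pitch_events(
    events: list[PitchChangeEvent], group_window_s: float = 23.3
) -> list[list[PitchChangeEvent]]:
    """Chain-group events: successive starts within the window share a group."""
    events = sorted(events, key=lambda e: e.time_s)
    groups: list[list[PitchChangeEvent]] = []
    for e in events:
        if groups and e.time_s - groups[-1][-1].time_s <= group_window_s:
            groups[-1].append(e)
        else:
            groups.append([e])
    return groups


def classify_dives(
    group: list[PitchChangeEvent],
    pitchseries: PitchSeries,
    profile: CalibrationProfile,
    ascent_window_s: float = 10.0,
    descent_margin_deg: float = 30.0,
) -> list[tuple[float, float]]:
    """Foraging dives inside one pitch-event group.

    A dive starts where pitch crosses below (median minimum PFM pitch -
    ``descent_margin_deg``) and ends at the first sample within
    ``ascent_window_s`` where pitch exceeds (median mean PFM pitch + 2x
    median PFM pitch variance); descents with no such recovery are not dives.
    """
    fs = pitchseries.fs
    p = pitchseries.pitch_deg
    lo = profile.pfm_pitch_min_med_deg - descent_margin_deg
    hi = profile.pfm_pitch_mean_med_deg + 2.0 * profile.pfm_pitch_var_med_deg2
    a = max(0, int(np.floor(group[0].time_s * fs)))
    b = min(len(p), int(np.ceil((group[-1].end_time_s + ascent_window_s) * fs)) + 1)
    dives: list[tuple[float, float]] = []
    i = a
    win = int(round(ascent_window_s * fs))
    while i < b:
        if p[i] < lo:
            j_end = min(b, i + win + 1)
            rec = np.flatnonzero(p[i:j_end] > hi)
            if len(rec):
                j = i + int(rec[0])
                dives.append((i / fs, (j + 1) / fs))
                i = j + 1
                continue
            # skip past this below-threshold excursion
            above = np.flatnonzero(p[i:b] >= lo)
            i = b if len(above) == 0 else i + int(above[0])
        else:
            i += 1
    return dives


def classify_surface_seizing(
    group: list[PitchChangeEvent],
    burst_gap_s: float = 2.0,
    min_events: int = 3,
    all_pairs: bool = False,
) -> list[tuple[float, float]]:
    """Surface-seizing spans: chains of >= ``min_events`` events <= ``burst_gap_s`` apart.

    Dives must already have been removed from the group.  With
    ``all_pairs=True`` the events of a burst must all lie within
    ``burst_gap_s`` of each other rather than chain-wise.
    """
    if not group:
        return []
    events = sorted(group, key=lambda e: e.time_s)
    spans: list[tuple[float, float]] = []
    if all_pairs:
        n = len(events)
        i = 0
        while i < n:
            j = i
            while (
                j + 1 < n
                and events[j + 1].time_s - events[i].time_s <= burst_gap_s
            ):
                j += 1
            if j - i + 1 >= min_events:
                spans.append((events[i].time_s, events[j].end_time_s))
            i = j + 1
    else:
        chain = [events[0]]
        for e in events[1:]:
            if e.time_s - chain[-1].time_s <= burst_gap_s:
                chain.append(e)
            else:
                if len(chain) >= min_events:
                    spans.append((chain[0].time_s, chain[-1].end_time_s))
                chain = [e]
        if len(chain) >= min_events:
            spans.append((chain[0].time_s, chain[-1].end_time_s))
    return _agglomerate(spans, 0.0, strict=False)


def classify_rest(
    odbaseries: OdbaSeries, threshold_g: float = 0.2
) -> list[tuple[float, float]]:
    """Maximal runs where the ODBA moving mean stays below the threshold.

    Exclusion of samples already claimed by higher-precedence behaviours
    happens at assembly time.
    """
    below = odbaseries.odmn < threshold_g
    if not below.any():
        return []
    d = np.diff(below.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        ends = np.concatenate((ends, [len(below)]))
    fs = odbaseries.fs
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


#: Painting order, lowest precedence first.
_PRECEDENCE = ("unknown", "rest", "flight", "take_off", "surface_seizing",
               "foraging_dive")


def assemble_ethogram(
    n_samples: int,
    fs: float,
    dives: list[tuple[float, float]],
    seizing: list[tuple[float, float]],
    takeoffs: list[tuple[float, float]],
    flights: list[tuple[float, float]],
    rests: list[tuple[float, float]],
    unknown_groups: list[tuple[float, float]] = (),
) -> Ethogram:
    """Resolve all detections into one non-overlapping, exhaustive ethogram.

    Each sample takes the highest-precedence claim (dive > surface seizing >
    take-off > flight > rest > unknown); unclaimed samples are unknown.
    """
    code = {lab: i for i, lab in enumerate(_PRECEDENCE)}
    labels = np.zeros(n_samples, dtype=np.int8)  # unknown
    layers = [
        ("unknown", unknown_groups),
        ("rest", rests),
        ("flight", flights),
        ("take_off", takeoffs),
        ("surface_seizing", seizing),
        ("foraging_dive", dives),
    ]
    for lab, spans in layers:
        c = code[lab]
        for s, e in spans:
            a = max(0, int(np.floor(s * fs)))
            b = min(n_samples, int(np.ceil(e * fs)))
            if b > a:
                labels[a:b] = np.maximum(labels[a:b], c)
    # run-length encode back into intervals
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], change, [n_samples]))
    intervals = [
        (a / fs, b / fs, _PRECEDENCE[labels[a]])
        for a, b in zip(bounds, bounds[1:])
    ]
    return Ethogram(intervals)


@dataclass
class ClassificationResult:
    """Full ethogram plus the intermediate detections that produced it."""

    ethogram: Ethogram
    flights: list[tuple[float, float]]
    takeoffs: list[tuple[float, float]]
    dives: list[tuple[float, float]]
    seizing: list[tuple[float, float]]
    rests: list[tuple[float, float]]
    events: list[PitchChangeEvent] = field(default_factory=list)


def classify(
    series: AccelSeries,
    profile: CalibrationProfile,
    config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Run the full detection pipeline on one acceleration record."""
    cfg = config or ClassifierConfig()
    dec = decompose(series, cutoff_hz=cfg.cutoff_hz, order=cfg.filter_order)
    ps = pitch(dec)
    ob = odba(dec, window_s=cfg.rest_window_s)

    flaps = detect_flaps(dec, profile)
    flights = group_flight(
        flaps, series.fs, cfg.intra_bout_gap_s, cfg.inter_bout_gap_s
    )
    events = pitch_change_events(ps, profile)
    takeoffs = detect_takeoffs(
        flights, events, profile, cfg.takeoff_search_window_s
    )
    groups = group_pitch_events(events, cfg.event_group_window_s)

    dives: list[tuple[float, float]] = []
    seizing: list[tuple[float, float]] = []
    unknown_groups: list[tuple[float, float]] = []
    for g in groups:
        g_dives = classify_dives(
            g, ps, profile, cfg.dive_ascent_window_s, cfg.dive_descent_margin_deg
        )
        dives.extend(g_dives)
        # dives are removed before the surface-seizing chain is evaluated
        remaining = [
            e
            for e in g
            if not any(s <= e.time_s < t for s, t in g_dives)
        ]
        g_seiz = classify_surface_seizing(
            remaining, cfg.seize_burst_gap_s, cfg.seize_min_events,
            cfg.seize_all_pairs,
        )
        seizing.extend(g_seiz)
        if not g_dives and not g_seiz:
            unknown_groups.append((g[0].time_s, g[-1].end_time_s))

    rests = classify_rest(ob, cfg.rest_threshold_g)
    eth = assemble_ethogram(
        series.n, series.fs, dives, seizing, takeoffs, flights, rests,
        unknown_groups,
    )
    return ClassificationResult(
        ethogram=eth,
        flights=flights,
        takeoffs=takeoffs,
        dives=dives,
        seizing=seizing,
        rests=rests,
        events=events,
    )
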