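"""Labelled synthetic tag data: tri-axial acceleration, ethograms, GPS tracks.

The generator emits deterministic behaviour templates plus Gaussian noise,
with the statistical structure the detector assumes:

* flight — ~4 Hz flapping bursts on the dynamic dorsoventral channel
  interleaved with low-motion glides, small slow pitch wobble;
* take-off — faster (>5 Hz), larger-amplitude flapping with a large upward
  pitch excursion originating at low pitch (bird sitting on the water);
* foraging dive — a steep pitch drop well below -30 deg, a short submerged
  hold, then recovery to a positive pitch, ~3.2 s in total;
* surface seizing — alternating short landings (~1.5 s) and even shorter
  take-offs (~0.6 s), producing rapid large pitch swings < 2 s apart;
* rest — low-variance noise around a gravity-consistent static posture.

The static channel is always consistent with the scripted pitch
(x = sin(pitch) + noise), so the pitch estimator inverts the generator
exactly in the noise-free limit.  Every deployment uses a single seeded RNG
stream; output is byte-identical across runs for a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AccelSeries, Ethogram, GpsTrack, TagKind


@dataclass
class GeneratorConfig:
    """Signal-shape parameters of the generator (durations s, amplitudes g)."""

    fs: float = 20.0
    flight_flap_hz: float = 4.0
    takeoff_flap_hz: float = 5.5
    flap_amp_g: float = 0.4           # sinusoid amplitude; peak-trough ~0.8 g
    takeoff_amp_g: float = 0.6
    glide_noise_g: float = 0.025      # dorsoventral noise during glides
    rest_noise_g: float = 0.02        # per-axis dynamic noise at rest
    axis_noise_g: float = 0.02        # x/y dynamic noise in all behaviours
    flap_run_s: tuple[float, float] = (6.0, 10.0)
    glide_s: tuple[float, float] = (2.0, 3.5)
    dive_duration_mean_s: float = 3.2
    dive_duration_sd_s: float = 1.2
    landing_mean_s: float = 1.5
    landing_sd_s: float = 1.4
    seize_takeoff_mean_s: float = 0.6
    seize_takeoff_sd_s: float = 1.6
    preflight_takeoff_mean_s: float = 3.0
    preflight_takeoff_sd_s: float = 1.3
    dive_pitch_deg: float = -70.0
    dive_recovery_pitch_deg: float = 20.0
    seize_pitch_deg: float = 25.0
    takeoff_pitch_deg: float = 40.0
    takeoff_origin_pitch_deg: float = -10.0
    flight_pitch_wobble_deg: float = 3.0
    flight_pitch_wobble_hz: float = 0.3
    splash_noise_g: float = 0.08
    mount_pitch_offset_deg: float = 0.0
    tag_kind: TagKind = TagKind.chest_mounted

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.flight_flap_hz >= self.fs / 2:
            raise ValueError("flight flap frequency must be below Nyquist")
        for name in ("flap_amp_g", "takeoff_amp_g", "glide_noise_g",
                     "rest_noise_g", "dive_duration_mean_s", "landing_mean_s",
                     "seize_takeoff_mean_s", "preflight_takeoff_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.tag_kind, str):
            self.tag_kind = TagKind(self.tag_kind)


@dataclass
class BehaviourScript:
    """Ordered behaviour segments to synthesise: (label, duration_s, params)."""

    segments: list[tuple[str, float, dict]] = None
    seed: int = 0

    def __init__(self, segments, seed: int = 0):
        norm = []
        for seg in segments:
            if len(seg) == 2:
                lab, dur = seg
                params: dict = {}
            else:
                lab, dur, params = seg
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            norm.append((str(lab), float(dur), dict(params)))
        self.segments = norm
        self.seed = int(seed)

    @property
    def duration_s(self) -> float:
        return sum(d for _, d, _ in self.segments)


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(64):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


# --- per-behaviour template builders: return (pitch_deg, z_dyn) arrays ------

def _seg_rest(n, fs, rng, cfg):
    t = np.arange(n) / fs
    pitch = 1.0 * np.sin(2 * math.pi * 0.05 * t + rng.uniform(0, 2 * math.pi))
    z = rng.normal(0.0, cfg.rest_noise_g, n)
    return pitch, z


def _seg_flight(n, fs, rng, cfg):
    t = np.arange(n) / fs
    pitch = cfg.flight_pitch_wobble_deg * np.sin(
        2 * math.pi * cfg.flight_pitch_wobble_hz * t + rng.uniform(0, 2 * math.pi)
    )
    z = rng.normal(0.0, cfg.glide_noise_g, n)
    # alternate flap runs and glides, beginning and ending with flapping
    i = 0
    flapping = True
    while i < n:
        if flapping:
            run = int(rng.uniform(*cfg.flap_run_s) * fs)
            j = min(n, i + run)
            tt = np.arange(j - i) / fs
            z[i:j] += cfg.flap_amp_g * np.sin(2 * math.pi * cfg.flight_flap_hz * tt)
            i = j
        else:
            gap = int(rng.uniform(*cfg.glide_s) * fs)
            remaining = n - i
            # never end the segment on a glide
            if remaining <= gap + int(cfg.flap_run_s[0] * fs):
                run_t = np.arange(remaining) / fs
                z[i:] += cfg.flap_amp_g * np.sin(
                    2 * math.pi * cfg.flight_flap_hz * run_t
                )
                break
            i += gap
        flapping = not flapping
    return pitch, z


def _seg_takeoff(n, fs, rng, cfg):
    t = np.arange(n) / fs
    o = cfg.takeoff_origin_pitch_deg
    pitch = o + (cfg.takeoff_pitch_deg - o) * np.sin(math.pi * np.arange(n) / max(n - 1, 1))
    z = cfg.takeoff_amp_g * np.sin(2 * math.pi * cfg.takeoff_flap_hz * t)
    z += rng.normal(0.0, cfg.glide_noise_g, n)
    return pitch, z


def _seg_dive(n, fs, rng, cfg):
    frac = np.linspace(0.0, 1.0, n)
    lo, hi = cfg.dive_pitch_deg, cfg.dive_recovery_pitch_deg
    pitch = np.interp(
        frac,
        [0.0, 0.15, 0.55, 0.85, 0.95, 1.0],
        [0.0, lo, lo, hi, hi, 0.0],
    )
    z = rng.normal(0.0, 0.05, n)
    splash = slice(0, max(1, int(0.25 * n)))
    z[splash] += rng.normal(0.0, cfg.splash_noise_g, splash.stop)
    return pitch, z


def _seg_seizing(n, fs, rng, cfg):
    pitch = np.empty(n)
    z = np.empty(n)
    amp = cfg.seize_pitch_deg
    i = 0
    landing = True
    cur = amp  # enter from above the surface
    while i < n:
        if landing:
            dur = _truncnorm(rng, cfg.landing_mean_s, cfg.landing_sd_s, 0.5, 1.8)
            target = -amp
        else:
            dur = _truncnorm(rng, cfg.seize_takeoff_mean_s, cfg.seize_takeoff_sd_s,
                             0.3, 1.2)
            target = amp
        m = max(2, int(dur * fs))
        j = min(n, i + m)
        k = j - i
        # half-cosine swing from cur to target
        sw = cur + (target - cur) * (1 - np.cos(math.pi * np.arange(k) / max(m - 1, 1))) / 2
        pitch[i:j] = sw
        if landing:
            z[i:j] = rng.normal(0.0, cfg.splash_noise_g, k)
        else:
            tt = np.arange(k) / fs
            z[i:j] = cfg.takeoff_amp_g * 0.8 * np.sin(
                2 * math.pi * cfg.takeoff_flap_hz * tt
            ) + rng.normal(0.0, cfg.glide_noise_g, k)
        cur = sw[-1] if k else target
        i = j
        landing = not landing
    return pitch, z


_BUILDERS = {
    "rest": _seg_rest,
    "flight": _seg_flight,
    "take_off": _seg_takeoff,
    "foraging_dive": _seg_dive,
    "surface_seizing": _seg_seizing,
    "unknown": _seg_rest,   # unlabelled water-surface intervals look like rest
}


def synth_accel(
    script: BehaviourScript,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[AccelSeries, Ethogram]:
    """Synthesise a tri-axial record and its exact ground-truth ethogram."""
    cfg = config or GeneratorConfig()
    rng = rng or np.random.default_rng(script.seed)
    fs = cfg.fs
    pitches, zs, intervals = [], [], []
    t_cursor = 0.0
    for label, dur, params in script.segments:
        n = max(1, int(round(dur * fs)))
        seg_cfg = replace(cfg, **params) if params else cfg
        p, z = _BUILDERS[label](n, fs, rng, seg_cfg)
        pitches.append(p)
        zs.append(z)
        realised = n / fs
        intervals.append((t_cursor, t_cursor + realised, label))
        t_cursor += realised
    pitch_deg = np.concatenate(pitches) + cfg.mount_pitch_offset_deg
    z_dyn = np.concatenate(zs)
    n = len(pitch_deg)
    rad = np.radians(pitch_deg)
    x = np.sin(rad) + rng.normal(0.0, cfg.axis_noise_g, n)
    y = rng.normal(0.0, cfg.axis_noise_g, n)
    z = np.cos(rad) + z_dyn
    # merge adjacent intervals with equal labels into the truth ethogram
    merged: list[list] = []
    for s, e, l in intervals:
        if merged and merged[-1][2] == l and abs(merged[-1][1] - s) < 1e-9:
            merged[-1][1] = e
        else:
            merged.append([s, e, l])
    series = AccelSeries(fs=fs, x=x, y=y, z=z, tag_kind=cfg.tag_kind)
    return series, Ethogram([tuple(m) for m in merged])


def _dive_bout(rng, cfg, n_dives: int) -> list[tuple[str, float, dict]]:
    segs: list[tuple[str, float, dict]] = []
    for k in range(n_dives):
        d = _truncnorm(rng, cfg.dive_duration_mean_s, cfg.dive_duration_sd_s,
                       2.0, 6.0)
        segs.append(("foraging_dive", d, {}))
        if k < n_dives - 1:
            segs.append(("unknown", rng.uniform(4.0, 8.0), {}))
    return segs


def standard_foraging_script(
    duration_s: float = 7200.0,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> BehaviourScript:
    """A two-hour chest-tag-style deployment script.

    Roughly two thirds flight, a few percent surface seizing, under a minute
    of foraging dives and the remainder rest — the behavioural mix a
    shallow-diving shearwater shows over a video-length recording.  Foraging
    bouts are buffered by sit-on-water rests so flight never bridges them.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    segs: list[tuple[str, float, dict]] = [("rest", rng.uniform(120, 180), {})]

    def takeoff_dur():
        return _truncnorm(rng, cfg.preflight_takeoff_mean_s,
                          cfg.preflight_takeoff_sd_s, 2.0, 5.0)

    total = segs[0][1]
    while total < duration_s:
        cycle: list[tuple[str, float, dict]] = [
            ("take_off", takeoff_dur(), {}),
            ("flight", rng.uniform(240, 330), {}),
            ("surface_seizing", rng.uniform(35, 55), {}),
            ("rest", rng.uniform(60, 90), {}),
            ("take_off", takeoff_dur(), {}),
            ("flight", rng.uniform(240, 330), {}),
            ("rest", rng.uniform(90, 130), {}),
            *_dive_bout(rng, cfg, int(rng.integers(2, 4))),
            ("rest", rng.uniform(90, 130), {}),
        ]
        segs.extend(cycle)
        total += sum(d for _, d, _ in cycle)
    # trim the script back to the requested duration, dropping the overhang
    out, acc = [], 0.0
    for lab, dur, par in segs:
        if acc + dur >= duration_s:
            rem = duration_s - acc
            if rem > 1.0:
                out.append((lab, rem, par))
            break
        out.append((lab, dur, par))
        acc += dur
    return BehaviourScript(out, seed=seed)


# ---------------------------------------------------------------------------
# multi-day deployments with GPS
# ---------------------------------------------------------------------------

_SPEEDS_KPH = {
    "flight": 45.0,
    "take_off": 20.0,
    "rest": 1.5,
    "surface_seizing": 6.0,
    "foraging_dive": 4.0,
    "unknown": 4.0,
    "colony": 0.0,
}


def _at_sea_day_segments(rng, cfg, start_s: float, end_s: float):
    """Fill [start_s, end_s) of a day with at-sea behaviour cycles."""
    segs: list[tuple[str, float, dict]] = []
    total = start_s
    while total < end_s:
        cycle = [
            ("take_off", _truncnorm(rng, cfg.preflight_takeoff_mean_s,
                                    cfg.preflight_takeoff_sd_s, 2.0, 5.0), {}),
            ("flight", rng.uniform(1800, 2100), {}),
            ("rest", rng.uniform(80, 110), {}),
            ("surface_seizing", rng.uniform(35, 55), {}),
            ("rest", rng.uniform(80, 110), {}),
            ("take_off", _truncnorm(rng, cfg.preflight_takeoff_mean_s,
                                    cfg.preflight_takeoff_sd_s, 2.0, 5.0), {}),
            ("flight", rng.uniform(1800, 2100), {}),
            ("rest", rng.uniform(1200, 1500), {}),
            *_dive_bout(rng, cfg, int(rng.integers(2, 4))),
            ("rest", rng.uniform(1200, 1500), {}),
        ]
        for lab, dur, par in cycle:
            if total + dur >= end_s:
                rem = end_s - total
                if rem > 1.0:
                    segs.append((lab, rem, par))
                total = end_s
                break
            segs.append((lab, dur, par))
            total += dur
    return segs


def synth_deployment(
    trip_lengths_days: list[int],
    seed: int = 0,
    config: GeneratorConfig | None = None,
    include_accel: bool = True,
    fix_interval_s: float = 5.0,
    colony: tuple[float, float] = (39.402, 141.985),
    t0: str | pd.Timestamp = "2018-08-20 00:00:00",
    departure_h: float = 6.0,
    return_h: float = 20.0,
) -> tuple[AccelSeries | None, Ethogram, GpsTrack]:
    """Synthesise a multi-day deployment: behaviour script, signal, GPS track.

    Each trip occupies ``k`` consecutive calendar days (departing
    ``departure_h`` local on the first, returning ``return_h`` local on the
    last), separated by full days at the colony.  GPS fixes are generated
    every ``fix_interval_s`` with speeds consistent with the behaviour
    (flight ~45 kph, foraging well under 15 kph, rest drift, stationary at
    the colony).  With ``include_accel=False`` only the ethogram and track
    are produced, for long deployments where the raw signal is not needed.
    """
    cfg = config or GeneratorConfig(tag_kind=TagKind.back_mounted)
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(t0)

    # --- day plan: segments on the deployment clock (s from t0) -----------
    segs: list[tuple[str, float, dict]] = []
    trip_id = np.array([], dtype=int)   # parallel per-segment trip index, -1 colony
    seg_trip: list[int] = []

    day = 0
    for ti, k in enumerate(trip_lengths_days):
        # colony rest until departure on the first trip day
        segs.append(("rest", day * 86400.0 + departure_h * 3600.0
                     - sum(d for _, d, _ in segs), {"_colony": True}))
        seg_trip.append(-1)
        dep = day * 86400.0 + departure_h * 3600.0
        ret = (day + k - 1) * 86400.0 + return_h * 3600.0
        at_sea = _at_sea_day_segments(rng, cfg, dep, ret)
        segs.extend(at_sea)
        seg_trip.extend([ti] * len(at_sea))
        day += k
    # final colony rest to the end of the last day
    tail = day * 86400.0 - sum(d for _, d, _ in segs)
    if tail > 1.0:
        segs.append(("rest", tail, {"_colony": True}))
        seg_trip.append(-1)

    # strip private markers from params before handing to the signal builder
    colony_flags = [bool(p.pop("_colony", False)) for _, _, p in segs]
    script = BehaviourScript(segs, seed=seed)

    ethogram = _script_ethogram(script)
    track = _simulate_track(
        script, colony_flags, seg_trip, rng, colony, t0, fix_interval_s
    )

    series = None
    if include_accel:
        series, ethogram = synth_accel(script, cfg, rng=np.random.default_rng(seed + 1))
        series.t0 = t0
    return series, ethogram, track


def _script_ethogram(script: BehaviourScript) -> Ethogram:
    intervals, t = [], 0.0
    for lab, dur, _ in script.segments:
        if intervals and intervals[-1][2] == lab:
            intervals[-1][1] = t + dur
        else:
            intervals.append([t, t + dur, lab])
        t += dur
    return Ethogram([tuple(iv) for iv in intervals])


def _simulate_track(script, colony_flags, seg_trip, rng, colony, t0,
                    fix_interval_s) -> GpsTrack:
    """Step a kinematic position model along the script at the fix rate."""
    # remaining flight seconds per trip, to time the inbound turn
    flight_left: dict[int, float] = {}
    for (lab, dur, _), ti in zip(script.segments, seg_trip):
        if ti >= 0 and lab == "flight":
            flight_left[ti] = flight_left.get(ti, 0.0) + dur

    km_per_deg_lat = 110.574
    times, lats, lons = [], [], []
    x_km, y_km = 0.0, 0.0       # east/north offsets from the colony
    t = 0.0
    dt = fix_interval_s
    bearings = {ti: rng.uniform(0, 2 * math.pi) for ti in flight_left}
    drift_heading = rng.uniform(0, 2 * math.pi)
    arrived: dict[int, bool] = {ti: False for ti in flight_left}

    for (lab, dur, _), at_colony, ti in zip(script.segments, colony_flags, seg_trip):
        n_fix = int(dur // dt)
        for _ in range(n_fix):
            if at_colony:
                x_km, y_km = 0.0, 0.0
                jx, jy = rng.normal(0, 0.02, 2)
                px, py = jx, jy
            else:
                speed = _SPEEDS_KPH[lab]
                dist_home = math.hypot(x_km, y_km)
                if lab == "flight":
                    step = speed * dt / 3600.0
                    inbound = flight_left[ti] <= (dist_home / 45.0) * 3600.0 * 1.15
                    if arrived[ti] or (inbound and dist_home < 2.2):
                        arrived[ti] = True
                        # circle just outside the colony awaiting the script end
                        theta = math.atan2(y_km, x_km) + 0.02
                        x_km, y_km = 2.5 * math.cos(theta), 2.5 * math.sin(theta)
                    elif inbound:
                        f = min(1.0, step / max(dist_home, 1e-9))
                        x_km -= f * x_km
                        y_km -= f * y_km
                    else:
                        b = bearings[ti] + rng.normal(0, 0.05)
                        x_km += step * math.sin(b)
                        y_km += step * math.cos(b)
                    flight_left[ti] -= dt
                else:
                    drift_heading += rng.normal(0, 0.3)
                    step = speed * dt / 3600.0
                    x_km += step * math.sin(drift_heading)
                    y_km += step * math.cos(drift_heading)
                    # drifting birds never wander back inside the colony radius
                    d = math.hypot(x_km, y_km)
                    if 0 < d < 2.0:
                        x_km, y_km = 2.0 * x_km / d, 2.0 * y_km / d
                px, py = x_km, y_km
            lat = colony[0] + py / km_per_deg_lat
            lon = colony[1] + px / (111.320 * math.cos(math.radians(colony[0])))
            times.append(t)
            lats.append(lat)
            lons.append(lon)
            t += dt
        # segment remainder shorter than one fix interval emits no fix
        t += dur - n_fix * dt
    df = pd.DataFrame(
        {
            "time": t0 + pd.to_timedelta(np.array(times), unit="s"),
            "lat": lats,
            "lon": lons,
        }
    )
    return GpsTrack(df)
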