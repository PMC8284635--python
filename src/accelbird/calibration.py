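"""Per-tag threshold calibration from predicted flight minutes (PFMs).

Because mounting position (chest vs back) changes the recorded signal, no
fixed flap-amplitude or pitch thresholds transfer across tags.  Instead,
minutes of probable cruising flight are found spectrally — the minutes where
flapping-band energy most exceeds take-off-band energy — and every threshold
is derived from the signal inside those minutes:

* the flap amplitude threshold is the trough of a bimodal kernel density of
  dorsoventral peak-trough differences (flapping vs gliding modes);
* the "large pitch change" threshold is 1.5x the median of the per-PFM
  maximum successive pitch-extremum differences;
* dive detection uses the medians of per-PFM minimum pitch, mean pitch and
  pitch variance.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.stats

from .io import AccelSeries, TagKind
from .signal import (
    BandEnergySeries,
    DecomposedSeries,
    PitchSeries,
    band_energy,
    decompose,
    local_extrema,
    pitch,
)


class CalibrationError(RuntimeError):
    """Raised when the record cannot support threshold calibration."""


@dataclass
class CalibrationProfile:
    """Per-tag thresholds and PFM pitch statistics used by every rule."""

    pfm_windows: list[tuple[float, float]]
    flap_threshold_g: float
    large_pitch_change_deg: float
    pfm_pitch_min_med_deg: float
    pfm_pitch_mean_med_deg: float
    pfm_pitch_var_med_deg2: float
    tag_kind: TagKind = TagKind.chest_mounted
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.tag_kind, str):
            self.tag_kind = TagKind(self.tag_kind)
        if self.flap_threshold_g <= 0:
            raise ValueError("flap threshold must be positive")
        if self.large_pitch_change_deg <= 0:
            raise ValueError("large pitch change threshold must be positive")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["tag_kind"] = self.tag_kind.value
        d["pfm_windows"] = [list(w) for w in self.pfm_windows]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationProfile":
        with open(path) as fh:
            d = json.load(fh)
        d["pfm_windows"] = [tuple(w) for w in d["pfm_windows"]]
        return cls(**d)


def select_pfms(
    bands: BandEnergySeries,
    n_pfm: int,
    min_separation_s: float = 300.0,
    window_s: float = 60.0,
) -> list[tuple[float, float]]:
    """Select predicted flight minutes from band-energy differences.

    The flap-minus-takeoff energy difference is summed in one-minute moving
    windows (hop of one spectrogram frame).  Windows are taken greedily in
    descending order of summed difference, rejecting any window whose start
    lies within ``min_separation_s`` of an already selected start; ties break
    to the earliest start.  If fewer than ``n_pfm`` windows are eligible a
    warning is emitted and the shorter list returned.
    """
    t = bands.frame_times
    d = bands.diff
    # the hop is one frame, so a window is a fixed frame count; computing
    # membership by count (not by float time comparison) keeps ties exact
    k = max(1, int(round(window_s / bands.frame_hop_s)))
    if len(t) < k:
        warnings.warn("record shorter than one PFM window", stacklevel=2)
        return []
    csum = np.concatenate(([0.0], np.cumsum(d)))
    sums = csum[k:] - csum[:-k]
    starts = t[: len(sums)]
    order = np.lexsort((starts, -sums))  # descending sum, earliest on ties
    chosen: list[float] = []
    for i in order:
        s = starts[i]
        if all(abs(s - c) >= min_separation_s for c in chosen):
            chosen.append(s)
            if len(chosen) == n_pfm:
                break
    if len(chosen) < n_pfm:
        warnings.warn(
            f"only {len(chosen)} of {n_pfm} requested PFMs were separable "
            f"by {min_separation_s} s",
            stacklevel=2,
        )
    return [(s, s + window_s) for s in sorted(chosen)]


def _window_slice(n: int, fs: float, window: tuple[float, float]) -> slice:
    a = max(0, int(np.ceil(window[0] * fs)))
    b = min(n, int(np.ceil(window[1] * fs)))
    return slice(a, b)


def kde_trough(samples: np.ndarray, grid_points: int = 512) -> float | None:
    """Density minimum between the two largest modes of a 1-D sample.

    A Gaussian kernel density estimate with the normal-reference (Silverman)
    bandwidth is evaluated on a ``grid_points`` grid spanning the data range;
    the trough is the lowest-density abscissa strictly between the two
    highest interior modes (first such point on ties).  Returns ``None`` for
    effectively unimodal samples.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 4 or np.ptp(samples) == 0:
        return None
    kde = scipy.stats.gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(samples.min(), samples.max(), grid_points)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    if len(interior) < 2:
        return None
    if len(interior) > 2:
        warnings.warn(
            f"flap amplitude density has {len(interior)} modes; "
            "using the two largest",
            stacklevel=2,
        )
    top2 = interior[np.argsort(dens[interior], kind="stable")[-2:]]
    lo, hi = sorted(top2)
    between = slice(lo + 1, hi)
    if between.start >= between.stop:
        return None
    return float(grid[between][np.argmin(dens[between])])


def extremum_differences(signal: np.ndarray) -> np.ndarray:
    """Absolute differences between successive alternating local extrema."""
    ext = local_extrema(signal)
    if len(ext) < 2:
        return np.array([])
    return np.abs(np.diff(ext.values))


def flap_threshold(
    decomposed: DecomposedSeries, pfms: list[tuple[float, float]]
) -> float:
    """Flap-amplitude threshold: median of per-PFM KDE troughs.

    For each PFM the peak-trough differences of dynamic dorsoventral
    acceleration form a bimodal distribution (flapping and gliding); the
    kernel-density trough between its two largest modes separates them.
    PFMs whose density is unimodal are skipped; if all are skipped a
    :class:`CalibrationError` is raised.
    """
    troughs = []
    for w in pfms:
        seg = decomposed.z_d[_window_slice(decomposed.n, decomposed.fs, w)]
        if len(seg) < 3:
            continue
        diffs = extremum_differences(seg)
        if len(diffs) < 2:
            continue
        tr = kde_trough(diffs)
        if tr is not None:
            troughs.append(tr)
    if not troughs:
        raise CalibrationError(
            "no PFM produced a bimodal flap/glide amplitude density"
        )
    return float(np.median(troughs))


def pitch_statistics(
    pitchseries: PitchSeries, pfms: list[tuple[float, float]]
) -> tuple[float, float, float, float]:
    """PFM pitch statistics feeding the take-off and dive rules.

    Per PFM: (a) the maximum successive pitch-extremum difference, (b) the
    minimum pitch, (c) the mean pitch, (d) the population pitch variance.
    Returns ``(1.5 * median(a), median(b), median(c), median(d))``.  PFMs
    with fewer than two pitch extrema contribute no (a) term (warning); if
    none contribute, calibration fails.
    """
    if not pfms:
        raise CalibrationError("no PFM windows supplied")
    max_diffs, mins, means, variances = [], [], [], []
    n_skipped = 0
    for w in pfms:
        seg = pitchseries.pitch_deg[
            _window_slice(len(pitchseries.pitch_deg), pitchseries.fs, w)
        ]
        if len(seg) == 0:
            continue
        mins.append(float(seg.min()))
        means.append(float(seg.mean()))
        variances.append(float(seg.var()))  # population variance
        diffs = extremum_differences(seg) if len(seg) >= 3 else np.array([])
        if len(diffs):
            max_diffs.append(float(diffs.max()))
        else:
            n_skipped += 1
    if n_skipped:
        warnings.warn(
            f"{n_skipped} PFM(s) had fewer than two pitch extrema", stacklevel=2
        )
    if not max_diffs:
        raise CalibrationError(
            "no PFM contained pitch extrema; large-pitch-change threshold undefined"
        )
    return (
        1.5 * float(np.median(max_diffs)),
        float(np.median(mins)),
        float(np.median(means)),
        float(np.median(variances)),
    )


def pool_dvl_pitch_threshold(profiles: list[CalibrationProfile]) -> float:
    """Pooled large-pitch-change threshold for chest-mounted (video) tags.

    Each video tag records only ~2 h, so its own threshold is noisy; the
    median across all chest-mounted profiles is used instead.
    """
    vals = [
        p.large_pitch_change_deg
        for p in profiles
        if p.tag_kind is TagKind.chest_mounted
    ]
    if not vals:
        raise CalibrationError("no chest-mounted profiles to pool")
    return float(np.median(vals))


def calibrate(
    series: AccelSeries,
    n_pfm: int | None = None,
    min_separation_s: float = 300.0,
    cutoff_hz: float = 1.5,
    order: int = 100,
    window_s: float = 4.0,
    overlap_frac: float = 0.85,
) -> CalibrationProfile:
    """End-to-end calibration of one tag record.

    ``n_pfm`` defaults to 10 for chest-mounted recordings and 20 per calendar
    day (final partial day pro-rated, rounded up, minimum 1) for back-mounted
    multi-day recordings.
    """
    if n_pfm is None:
        if series.tag_kind is TagKind.chest_mounted:
            n_pfm = 10
        else:
            days = series.duration_s / 86400.0
            whole = int(days)
            frac = days - whole
            n_pfm = 20 * whole
            if frac > 0:
                n_pfm += max(1, int(np.ceil(20 * frac)))
            n_pfm = max(1, n_pfm)
    dec = decompose(series, cutoff_hz=cutoff_hz, order=order)
    bands = band_energy(dec, window_s=window_s, overlap_frac=overlap_frac)
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        pfms = select_pfms(bands, n_pfm=n_pfm, min_separation_s=min_separation_s)
        thr = flap_threshold(dec, pfms)
        big_pitch, p_min, p_mean, p_var = pitch_statistics(pitch(dec), pfms)
        notes = [str(w.message) for w in caught]
    return CalibrationProfile(
        pfm_windows=pfms,
        flap_threshold_g=thr,
        large_pitch_change_deg=big_pitch,
        pfm_pitch_min_med_deg=p_min,
        pfm_pitch_mean_med_deg=p_mean,
        pfm_pitch_var_med_deg2=p_var,
        tag_kind=series.tag_kind,
        warnings=notes,
    )
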