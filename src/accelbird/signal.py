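"""Core signal primitives for behaviour detection from body acceleration.

Raw acceleration is split into a *static* component (gravity/posture, the
low-frequency part) and a *dynamic* component (propulsive motion, the
residual).  Body pitch is the arcsine of static longitudinal acceleration;
ODBA (overall dynamic body acceleration) is the L1 norm of the dynamic
components and serves as a movement-intensity proxy.  Flapping shows up as
band-limited energy in the dynamic dorsoventral channel, which a short-time
Fourier transform localises in time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .io import AccelSeries


@dataclass
class DecomposedSeries:
    """Static/dynamic decomposition of a tri-axial record.

    Invariant: ``static + dynamic == raw`` per axis to floating tolerance,
    because dynamic is defined as the subtraction residual.
    """

    fs: float
    x_s: np.ndarray
    y_s: np.ndarray
    z_s: np.ndarray
    x_d: np.ndarray
    y_d: np.ndarray
    z_d: np.ndarray

    @property
    def n(self) -> int:
        return len(self.x_s)


@dataclass
class PitchSeries:
    """Per-sample body pitch in degrees, in [-90, +90]."""

    pitch_deg: np.ndarray
    fs: float


@dataclass
class OdbaSeries:
    """Per-sample ODBA and its moving average (both in g, non-negative)."""

    odba: np.ndarray
    odmn: np.ndarray
    fs: float


@dataclass
class BandEnergySeries:
    """Per-frame summed spectral energy density in two flapping bands.

    ``diff`` is flapping-flight band minus take-off band; positive values
    indicate cruising-flight wingbeat frequencies dominating.
    """

    frame_times: np.ndarray
    flap_band_energy: np.ndarray
    takeoff_band_energy: np.ndarray
    diff: np.ndarray
    fs: float
    frame_hop_s: float


@dataclass
class Extrema:
    """Strictly alternating local maxima/minima of a sampled signal."""

    indices: np.ndarray   # sample indices
    values: np.ndarray
    is_max: np.ndarray    # bool, True for maxima

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        for i, v, m in zip(self.indices, self.values, self.is_max):
            yield int(i), float(v), ("max" if m else "min")


def decompose(
    series: AccelSeries,
    cutoff_hz: float = 1.5,
    order: int = 100,
    zero_phase: bool = True,
) -> DecomposedSeries:
    """Split raw acceleration into static and dynamic components.

    Static acceleration is the raw signal low-pass filtered at ``cutoff_hz``
    with a linear-phase FIR (windowed-sinc, Hamming, ``order`` taps beyond the
    first, i.e. ``order + 1`` coefficients), applied forward-backward for zero
    phase so posture stays time-aligned.  Dynamic acceleration is raw minus
    static, which makes the reconstruction identity exact by construction.
    """
    ntaps = order + 1
    if series.n <= order:
        raise ValueError(
            f"series of {series.n} samples is shorter than the filter order {order}"
        )
    b = scipy.signal.firwin(ntaps, cutoff_hz, fs=series.fs, window="hamming")
    if zero_phase:
        padlen = min(3 * ntaps, series.n - 1)
        def lp(a):
            return scipy.signal.filtfilt(b, [1.0], a, padlen=padlen)
    else:
        def lp(a):
            return scipy.signal.lfilter(b, [1.0], a)
    x_s, y_s, z_s = lp(series.x), lp(series.y), lp(series.z)
    return DecomposedSeries(
        fs=series.fs,
        x_s=x_s, y_s=y_s, z_s=z_s,
        x_d=series.x - x_s, y_d=series.y - y_s, z_d=series.z - z_s,
    )


def pitch(decomposed: DecomposedSeries) -> PitchSeries:
    """Body pitch in degrees: arcsin of static longitudinal acceleration.

    Filter overshoot can push static x marginally outside [-1, 1]; it is
    clipped first, so the operation is total.
    """
    xs = np.clip(decomposed.x_s, -1.0, 1.0)
    return PitchSeries(pitch_deg=np.degrees(np.arcsin(xs)), fs=decomposed.fs)


def odba(decomposed: DecomposedSeries, window_s: float = 10.0) -> OdbaSeries:
    """ODBA (sum of absolute dynamic acceleration per axis) and its moving mean.

    The moving mean is centred over ``window_s`` seconds with shrinking
    windows at the edges (no padding).
    """
    vals = np.abs(decomposed.x_d) + np.abs(decomposed.y_d) + np.abs(decomposed.z_d)
    win = max(1, int(round(window_s * decomposed.fs)))
    odmn = (
        pd.Series(vals).rolling(win, center=True, min_periods=1).mean().to_numpy()
    )
    return OdbaSeries(odba=vals, odmn=odmn, fs=decomposed.fs)


def local_extrema(signal: np.ndarray) -> Extrema:
    """Alternating local maxima and minima of a 1-D signal.

    Plateaus collapse to a single extremum at their first sample, which
    guarantees strict max/min alternation.  A monotone (or constant) signal
    has no extrema.
    """
    a = np.asarray(signal, dtype=float)
    if a.ndim != 1 or len(a) < 3:
        raise ValueError("need a 1-D signal of length >= 3")
    # collapse runs of equal values to their first sample
    keep = np.concatenate(([True], np.diff(a) != 0))
    idx = np.flatnonzero(keep)
    v = a[idx]
    if len(v) < 3:
        return Extrema(np.array([], int), np.array([]), np.array([], bool))
    s = np.sign(np.diff(v))
    turn = s[:-1] != s[1:]
    where = np.flatnonzero(turn) + 1
    return Extrema(indices=idx[where], values=v[where], is_max=s[where - 1] > 0)


def band_energy(
    decomposed: DecomposedSeries,
    window_s: float = 4.0,
    overlap_frac: float = 0.85,
    flap_band: tuple[float, float] = (3.5, 5.0),
    takeoff_band: tuple[float, float] | None = None,
) -> BandEnergySeries:
    """Spectrogram band energies of dynamic dorsoventral acceleration.

    A Hann-windowed short-time Fourier transform (one-sided PSD scaling) over
    ``window_s`` windows with ``overlap_frac`` overlap; per frame, spectral
    energy density is summed inside the flapping-flight band (3.5-5 Hz,
    closed: a bin at exactly 5 Hz belongs to the flap band) and the take-off
    band (above 5 Hz up to Nyquist).  ``diff`` is flap minus take-off.
    """
    fs = decomposed.fs
    if takeoff_band is None:
        takeoff_band = (flap_band[1], fs / 2.0)
    if takeoff_band[0] >= fs / 2.0:
        raise ValueError(f"take-off band empty at fs={fs} Hz; need fs >= 10 Hz")
    nperseg = int(round(window_s * fs))
    if decomposed.n < nperseg:
        raise ValueError(
            f"series of {decomposed.n} samples shorter than one {window_s} s window"
        )
    noverlap = int(round(overlap_frac * nperseg))
    f, t, sxx = scipy.signal.spectrogram(
        decomposed.z_d,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    in_flap = (f >= flap_band[0]) & (f <= flap_band[1])
    in_takeoff = (f > takeoff_band[0]) & (f <= takeoff_band[1])
    flap = sxx[in_flap].sum(axis=0)
    toff = sxx[in_takeoff].sum(axis=0)
    return BandEnergySeries(
        frame_times=t,
        flap_band_energy=flap,
        takeoff_band_energy=toff,
        diff=flap - toff,
        fs=fs,
        frame_hop_s=(nperseg - noverlap) / fs,
    )
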