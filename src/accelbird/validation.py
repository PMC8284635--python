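"""Duration-based validation of a predicted ethogram against a reference.

Both ethograms are sampled onto the acceleration clock (one label per
sample, e.g. every 0.05 s at 20 Hz) and, per behaviour, duration-based true
and false positive rates are computed:

    TPR = PF_c / V_F        FPR = PF_i / V_O

where PF_c is the duration predicted as the behaviour while the reference
agrees, V_F the total reference duration of the behaviour, PF_i the duration
predicted as the behaviour while the reference shows something else, and V_O
the total reference duration of all other behaviours.  A behaviour absent
from the reference has undefined TPR (reported as NaN / "NA").
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import Ethogram, LABELS


@dataclass
class BehaviourRates:
    """Eq-style confusion terms for one behaviour (durations in seconds)."""

    tpr: float   # NaN when V_F == 0
    fpr: float   # NaN when V_O == 0
    pf_c: float
    pf_i: float
    v_f: float
    v_o: float


@dataclass
class ValidationReport:
    """Per-behaviour TPR/FPR over a shared sample clock."""

    rates: dict[str, BehaviourRates]
    fs: float
    n_samples: int

    def to_table(self) -> dict[str, dict[str, float | str]]:
        """Rates as percentages, with 'NA' for undefined entries."""
        out: dict[str, dict[str, float | str]] = {}
        for lab, r in self.rates.items():
            out[lab] = {
                "TPR_pct": "NA" if math.isnan(r.tpr) else round(100 * r.tpr, 1),
                "FPR_pct": "NA" if math.isnan(r.fpr) else round(100 * r.fpr, 1),
            }
        return out


def sample_ethogram(
    ethogram: Ethogram, fs: float, duration_s: float | None = None
) -> np.ndarray:
    """Label at each sample instant ``k / fs``.

    Instants falling exactly on an interval boundary take the interval to
    the right (half-open convention).  Instants outside every interval read
    ``unknown``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration_s is None:
        duration_s = ethogram.end_s
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    labels = np.full(n, "unknown", dtype=object)
    if len(ethogram):
        starts = np.array([s for s, _, _ in ethogram.intervals])
        ends = np.array([e for _, e, _ in ethogram.intervals])
        labs = np.array([l for _, _, l in ethogram.intervals], dtype=object)
        idx = np.searchsorted(starts, t, side="right") - 1
        ok = (idx >= 0) & (t < ends[np.clip(idx, 0, None)])
        labels[ok] = labs[idx[ok]]
    return labels


def confusion_rates(
    predicted: np.ndarray, reference: np.ndarray, behaviour: str, fs: float
) -> BehaviourRates:
    """Duration-based TPR/FPR of one behaviour on a shared sample clock."""
    predicted = np.asarray(predicted, dtype=object)
    reference = np.asarray(reference, dtype=object)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference label sequences differ in length")
    dt = 1.0 / fs
    in_pred = predicted == behaviour
    in_ref = reference == behaviour
    pf_c = float(np.count_nonzero(in_pred & in_ref)) * dt
    pf_i = float(np.count_nonzero(in_pred & ~in_ref)) * dt
    v_f = float(np.count_nonzero(in_ref)) * dt
    v_o = float(np.count_nonzero(~in_ref)) * dt
    tpr = pf_c / v_f if v_f > 0 else math.nan
    fpr = pf_i / v_o if v_o > 0 else math.nan
    return BehaviourRates(tpr=tpr, fpr=fpr, pf_c=pf_c, pf_i=pf_i, v_f=v_f, v_o=v_o)


def exclude_periods(
    labels: np.ndarray, mask: list[tuple[float, float]], fs: float
) -> np.ndarray:
    """Drop samples whose instants fall inside any masked interval.

    Used to remove periods where the reference is unreliable (e.g. the video
    view was obscured) before computing rates; apply identically to both
    sequences to keep the clocks aligned.
    """
    labels = np.asarray(labels, dtype=object)
    t = np.arange(len(labels)) / fs
    keep = np.ones(len(labels), dtype=bool)
    for s, e in mask:
        keep &= ~((t >= s) & (t < e))
    return labels[keep]


def validate(
    predicted: Ethogram,
    reference: Ethogram,
    fs: float,
    mask: list[tuple[float, float]] | None = None,
    behaviours: tuple[str, ...] = LABELS,
    duration_s: float | None = None,
) -> ValidationReport:
    """Sample both ethograms and compute per-behaviour TPR/FPR."""
    if duration_s is None:
        duration_s = max(predicted.end_s, reference.end_s)
    pred = sample_ethogram(predicted, fs, duration_s)
    ref = sample_ethogram(reference, fs, duration_s)
    if mask:
        pred = exclude_periods(pred, mask, fs)
        ref = exclude_periods(ref, mask, fs)
    rates = {b: confusion_rates(pred, ref, b, fs) for b in behaviours}
    return ValidationReport(rates=rates, fs=fs, n_samples=len(pred))
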