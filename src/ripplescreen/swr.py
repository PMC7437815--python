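"""Sharp-wave ripple (SWR) detection and multi-unit verification.

SWRs are detected on the CA1 pyramidal-layer site as excursions of the
smoothed ripple-band (150–250 Hz) envelope exceeding ``threshold_sd``
standard deviations above the immobility baseline for at least
``min_duration_s``, restricted to qualified immobility. Event boundaries
are extended outward to the nearest crossing of the baseline mean; the
threshold-crossing time (``trigger_s``) is kept separately as t=0 for
peri-event slow-gamma windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert

from .preprocess import FilterKind, FilterSpec, IntervalSet, bandpass_filter

__all__ = [
    "DetectionParams",
    "EnvelopeStats",
    "RippleEvent",
    "ripple_envelope",
    "envelope_stats",
    "detect_swrs",
    "swr_abundance",
    "mua_spike_times",
    "mua_swr_modulation",
]


@dataclass(frozen=True)
class DetectionParams:
    """SWR detection parameters (defaults: 150–250 Hz band, 5 SD, >=15 ms).

    The robustness variants used in the field are the 125–250 Hz band and a
    3 SD threshold; both are plain parameter changes here.
    """

    band: tuple[float, float] = (150.0, 250.0)
    threshold_sd: float = 5.0
    min_duration_s: float = 0.015
    merge_gap_s: float = 0.015
    smoothing_sigma_s: float = 0.004

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0 or self.min_duration_s <= 0:
            raise ValueError("threshold_sd and min_duration_s must be positive")


@dataclass(frozen=True)
class EnvelopeStats:
    """Baseline mean/SD of the ripple envelope over immobility samples."""

    baseline_mean: float
    baseline_sd: float
    n_samples: int


@dataclass(frozen=True)
class RippleEvent:
    """One detected SWR.

    ``start_s``/``end_s`` are the mean-crossing extent of the excursion;
    ``trigger_s`` is the threshold-crossing onset used as t=0 for the 0–100 ms
    slow-gamma window; ``peak_sd`` is the envelope peak in baseline-SD units.
    """

    start_s: float
    peak_s: float
    end_s: float
    trigger_s: float
    peak_sd: float
    detection_site: str = ""

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def ripple_envelope(ripple_filtered: np.ndarray, sample_rate: float,
                    smoothing_sigma_s: float = 0.004) -> np.ndarray:
    """Magnitude of the analytic signal, Gaussian-smoothed (sigma 4 ms)."""
    x = np.asarray(ripple_filtered, dtype=float)
    env = np.abs(hilbert(x))
    if smoothing_sigma_s > 0:
        env = gaussian_filter1d(env, smoothing_sigma_s * sample_rate)
    return env


def envelope_stats(envelope: np.ndarray, immobility: IntervalSet, sample_rate: float) -> EnvelopeStats:
    """Baseline mean and SD over immobility samples only (single pass)."""
    if immobility.total_s <= 0:
        raise ValueError("empty immobility set: no baseline samples")
    mask = immobility.sample_mask(len(envelope), sample_rate)
    vals = np.asarray(envelope, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("immobility intervals fall outside the signal")
    mean = float(np.mean(vals))
    sd = float(np.std(vals))
    if sd <= 0:
        raise ValueError("zero baseline variance: degenerate envelope")
    return EnvelopeStats(baseline_mean=mean, baseline_sd=sd, n_samples=int(vals.size))


def detect_swrs(
    envelope: np.ndarray,
    stats: EnvelopeStats,
    params: DetectionParams,
    immobility: IntervalSet,
    sample_rate: float,
    detection_site: str = "",
) -> list[RippleEvent]:
    """Detect supra-threshold envelope excursions during immobility.

    Runs above ``baseline_mean + threshold_sd * baseline_sd`` within
    immobility are merged when separated by less than ``merge_gap_s`` and
    kept when the merged supra-threshold run lasts at least
    ``min_duration_s``. Start/end are then extended outward to the nearest
    baseline-mean crossing (clipped to the enclosing immobility interval).
    """
    env = np.asarray(envelope, dtype=float)
    n = len(env)
    thr = stats.baseline_mean + params.threshold_sd * stats.baseline_sd
    mask = (env > thr) & immobility.sample_mask(n, sample_rate)
    runs = _runs(mask)
    if not runs:
        return []
    # merge runs separated by < merge_gap_s
    gap = params.merge_gap_s * sample_rate
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = params.min_duration_s * sample_rate
    events: list[RippleEvent] = []
    intervals = immobility.intervals
    for s, e in merged:
        if e - s < min_len:
            continue
        trigger = s
        # enclosing immobility interval (sample indices)
        k = np.searchsorted(intervals[:, 0], s / sample_rate, side="right") - 1
        lo = int(np.ceil(intervals[k, 0] * sample_rate)) if k >= 0 else 0
        hi = min(n, int(np.ceil(intervals[k, 1] * sample_rate))) if k >= 0 else n
        start = s
        while start > lo and env[start - 1] > stats.baseline_mean:
            start -= 1
        end = e
        while end < hi and env[end] > stats.baseline_mean:
            end += 1
        peak = start + int(np.argmax(env[start:end]))
        events.append(
            RippleEvent(
                start_s=start / sample_rate,
                peak_s=peak / sample_rate,
                end_s=end / sample_rate,
                trigger_s=trigger / sample_rate,
                peak_sd=(env[peak] - stats.baseline_mean) / stats.baseline_sd,
                detection_site=detection_site,
            )
        )
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def swr_abundance(events: list[RippleEvent], immobility: IntervalSet) -> float:
    """SWR abundance in events per second of qualified immobility."""
    if immobility.total_s <= 0:
        raise ValueError("zero immobility time: abundance undefined")
    return len(events) / immobility.total_s


def mua_spike_times(
    wideband: np.ndarray,
    reference: np.ndarray,
    sample_rate: float,
    threshold_uv: float = 75.0,
    refractory_s: float = 0.001,
) -> np.ndarray:
    """Multi-unit spike times from a referenced wideband trace.

    The corpus-callosum reference is subtracted, the difference band-passed
    at 600–6000 Hz (Butterworth), and upward crossings of ``threshold_uv``
    with a 1 ms refractory period returned (seconds).
    """
    w = np.asarray(wideband, dtype=float)
    r = np.asarray(reference, dtype=float)
    if w.shape != r.shape:
        raise ValueError("wideband and reference must have equal length")
    if sample_rate < 20000:
        raise ValueError("multi-unit detection requires >= 20 kHz input")
    spec = FilterSpec(FilterKind.BUTTER_BANDPASS, 600.0, 6000.0, 4)
    filt = bandpass_filter(w - r, spec, sample_rate)
    above = filt > threshold_uv
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if crossings.size == 0:
        return np.empty(0)
    refr = refractory_s * sample_rate
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= refr:
            kept.append(c)
    return np.asarray(kept, dtype=float) / sample_rate


def mua_swr_modulation(
    spikes: np.ndarray,
    events: list[RippleEvent],
    immobility: IntervalSet,
    window_s: float = 0.1,
) -> float:
    """Ratio of spike rate within SWR windows to the immobility rate outside.

    The SWR window is [trigger, trigger + 0.1 s]. A ratio > 1 indicates
    SWR-modulated firing (the pyramidal-layer placement check). Returns
    ``inf`` when all immobility spikes fall inside event windows.
    """
    if immobility.total_s <= 0:
        raise ValueError("zero immobility time")
    if not events:
        raise ValueError("no events: modulation undefined")
    spikes = np.asarray(spikes, dtype=float)
    windows = IntervalSet(_disjoint_windows(events, window_s))
    in_mob = immobility.contains(spikes)
    in_win = windows.contains(spikes)
    t_win = windows.total_s
    t_out = immobility.total_s - t_win
    n_in = int(np.sum(in_win))
    n_out = int(np.sum(in_mob & ~in_win))
    rate_in = n_in / t_win
    if n_out == 0:
        return math.inf
    rate_out = n_out / t_out
    return rate_in / rate_out


def _disjoint_windows(events: list[RippleEvent], window_s: float) -> list[tuple[float, float]]:
    raw = sorted((ev.trigger_s, ev.trigger_s + window_s) for ev in events)
    out = [list(raw[0])]
    for s, e in raw[1:]:
        if s < out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(w) for w in out]
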