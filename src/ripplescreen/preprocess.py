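"""LFP preprocessing: filtering, downsampling, velocity, and immobility.

Event analysis downstream is restricted to *qualified immobility*: the part
of each low-speed run that follows 30 s of sustained sub-threshold speed
(Gaussian-smoothed speed < 1 cm/s). A session enters the dataset only if it
contains at least 10 min of such time out of a 60 min recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "FilterKind",
    "FilterSpec",
    "IntervalSet",
    "VelocitySeries",
    "bandpass_filter",
    "downsample",
    "velocity_from_position",
    "immobility_intervals",
    "session_passes_inclusion",
]


class FilterKind(str, Enum):
    BUTTER_BANDPASS = "BUTTER_BANDPASS"
    FIR_EQUIRIPPLE_BANDPASS = "FIR_EQUIRIPPLE_BANDPASS"


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter description.

    For Butterworth, ``order_or_transition`` is the filter order (default 4,
    applied forward-backward so the effective order doubles and phase is
    zero). For equiripple FIR it is the transition-band width in Hz.
    """

    kind: FilterKind
    low_hz: float
    high_hz: float
    order_or_transition: float = 4

    def validate(self, sample_rate: float) -> None:
        if not (0 < self.low_hz < self.high_hz < sample_rate / 2):
            raise ValueError(
                f"band ({self.low_hz}, {self.high_hz}) Hz invalid for fs={sample_rate} Hz"
            )


class IntervalSet:
    """Sorted, disjoint, half-open [start, end) intervals in seconds."""

    def __init__(self, intervals) -> None:
        arr = np.asarray(list(intervals), dtype=float).reshape(-1, 2)
        if arr.size:
            order = np.argsort(arr[:, 0])
            arr = arr[order]
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError("interval with end <= start")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("overlapping intervals")
        self.intervals = arr

    @property
    def total_s(self) -> float:
        if not self.intervals.size:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside any interval (half-open)."""
        t = np.asarray(t, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for s, e in self.intervals:
            mask |= (t >= s) & (t < e)
        return mask

    def sample_mask(self, n_samples: int, sample_rate: float) -> np.ndarray:
        """Mask over a regular sample grid t = k / sample_rate."""
        mask = np.zeros(n_samples, dtype=bool)
        for s, e in self.intervals:
            i0 = max(0, int(np.ceil(s * sample_rate)))
            i1 = min(n_samples, int(np.ceil(e * sample_rate)))
            if i1 > i0:
                mask[i0:i1] = True
        return mask


@dataclass
class VelocitySeries:
    """Speed on the 30 Hz tracking grid, cm/s, non-negative."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have equal length")
        if np.any(self.v < 0):
            raise ValueError("speed must be non-negative")


def bandpass_filter(x: np.ndarray, spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Zero-phase band-pass filter (same length as the input).

    Butterworth is applied forward-backward (``sosfiltfilt``); equiripple FIR
    uses symmetric taps convolved with ``mode='same'``, which is inherently
    zero-phase (the group delay of a linear-phase filter is compensated by
    centring the kernel).
    """
    spec.validate(sample_rate)
    x = np.asarray(x, dtype=float)
    if spec.kind is FilterKind.BUTTER_BANDPASS:
        sos = sps.butter(
            int(spec.order_or_transition),
            [spec.low_hz, spec.high_hz],
            btype="bandpass",
            fs=sample_rate,
            output="sos",
        )
        return sps.sosfiltfilt(sos, x, axis=-1)
    taps = _remez_bandpass(spec, sample_rate)
    if x.shape[-1] <= 3 * len(taps) // 2:
        raise ValueError("signal too short for FIR band-pass")
    if x.ndim == 1:
        return np.convolve(x, taps, mode="same")
    return np.apply_along_axis(lambda row: np.convolve(row, taps, mode="same"), -1, x)


def _remez_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    trans = float(spec.order_or_transition) if spec.order_or_transition else 10.0
    lo, hi = spec.low_hz, spec.high_hz
    # tap count from a Harris-style estimate for >=40 dB stopband
    ntaps = int(np.ceil(40 / (22 * trans / fs) / 1.0)) | 1
    ntaps = max(ntaps, 65)
    bands = [0, max(lo - trans, 0.1), lo, hi, min(hi + trans, fs / 2 - 0.1), fs / 2]
    return sps.remez(ntaps, bands, [0, 1, 0], fs=fs)


def downsample(x: np.ndarray, sample_rate: float, target_rate: float) -> np.ndarray:
    """Anti-alias filter and decimate by an integer factor."""
    if target_rate > sample_rate:
        raise ValueError("target rate exceeds source rate")
    ratio = sample_rate / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(f"non-integer decimation ratio {ratio}")
    if q == 1:
        return np.asarray(x, dtype=float).copy()
    return sps.resample_poly(np.asarray(x, dtype=float), up=1, down=q, axis=-1)


def velocity_from_position(position: np.ndarray, smoothing_sigma_s: float = 0.25) -> VelocitySeries:
    """Gaussian-smoothed speed from a (t, x, y) track.

    Positions are smoothed with a Gaussian of the given sigma before central
    differencing (one-sided at the edges), so single-frame tracking glitches
    do not produce spikes.
    """
    pos = np.asarray(position, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 2:
        raise ValueError("position must be (n>=2, 3)")
    t, x, y = pos[:, 0], pos[:, 1], pos[:, 2]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    fps = 1.0 / np.median(dt)
    sigma_frames = max(smoothing_sigma_s * fps, 1e-9)
    xs = gaussian_filter1d(x, sigma_frames, mode="nearest")
    ys = gaussian_filter1d(y, sigma_frames, mode="nearest")
    vx = np.gradient(xs, t)
    vy = np.gradient(ys, t)
    return VelocitySeries(t=t, v=np.hypot(vx, vy))


def immobility_intervals(
    v: VelocitySeries,
    threshold_cm_s: float = 1.0,
    qualify_s: float = 30.0,
    count_whole_run: bool = False,
) -> IntervalSet:
    """Qualified-immobility intervals from a speed series.

    Each maximal run with speed below ``threshold_cm_s`` lasting at least
    ``qualify_s`` contributes ``[run_start + qualify_s, run_end)`` — analysis
    starts only *after* 30 s of sustained immobility. With
    ``count_whole_run=True`` the full run ``[run_start, run_end)`` is counted
    instead (the alternative reading of the inclusion rule).
    """
    below = v.v < threshold_cm_s
    t = v.t
    out: list[tuple[float, float]] = []
    n = len(below)
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            start = t[i]
            # run extends to the first above-threshold frame (half-open)
            end = t[j + 1] if j + 1 < n else t[-1] + (t[-1] - t[-2] if n > 1 else 0.0)
            if end - start >= qualify_s:
                out.append((start, end) if count_whole_run else (start + qualify_s, end))
            i = j + 1
        else:
            i += 1
    return IntervalSet(out)


def session_passes_inclusion(
    immobility: IntervalSet, min_total_s: float = 600.0, session_s: float = 3600.0
) -> bool:
    """Session inclusion: at least 10 min qualified immobility (boundary inclusive)."""
    return immobility.total_s >= min_total_s
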