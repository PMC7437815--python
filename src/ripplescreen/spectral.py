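"""Multitaper spectrograms and the SWR-associated slow-gamma power feature.

The feature of interest is the mean z-scored power in the slow-gamma band
(30–50 Hz) in the 0–100 ms window after each detected SWR, averaged over
events, then over electrode sites within a region, then over sessions, so
each mouse contributes a single number per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .preprocess import IntervalSet
from .swr import RippleEvent

__all__ = [
    "SpectrogramSpec",
    "PeriEventSpectrogram",
    "multitaper_spectrogram",
    "zscore_spectrogram",
    "sg_power_during_swrs",
    "peri_event_spectrogram",
    "aggregate_feature",
]

SG_BAND = (30.0, 50.0)
SG_WINDOW = (0.0, 0.1)


@dataclass(frozen=True)
class SpectrogramSpec:
    """Sliding-window multitaper parameters (100 ms window, 10 ms step,
    time-bandwidth 2 with 3 DPSS tapers by default)."""

    window_s: float = 0.1
    step_s: float = 0.01
    time_bandwidth: float = 2.0
    n_tapers: int = 3
    freq_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ValueError("n_tapers must be <= 2*NW - 1")


@dataclass
class PeriEventSpectrogram:
    """Event-triggered average z-scored spectrogram."""

    rel_time: np.ndarray
    freq: np.ndarray
    z: np.ndarray  # (time, freq)
    n_events: int


def multitaper_spectrogram(
    signal: np.ndarray, sample_rate: float, spec: SpectrogramSpec = SpectrogramSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window multitaper power.

    Returns ``(t_centers, freqs, power)`` with ``power`` of shape
    (n_windows, n_freqs) in uV^2/Hz (one-sided PSD, so band-integrated power
    over [0, fs/2] recovers the signal variance for stationary noise).
    """
    x = np.asarray(signal, dtype=float)
    nwin = int(round(spec.window_s * sample_rate))
    if nwin < 32:
        raise ValueError("window must span at least 32 samples")
    if len(x) < nwin:
        raise ValueError("signal shorter than one spectrogram window")
    step = max(1, int(round(spec.step_s * sample_rate)))
    tapers = dpss(nwin, spec.time_bandwidth, Kmax=spec.n_tapers)  # (K, nwin), unit energy
    starts = np.arange(0, len(x) - nwin + 1, step)
    freqs = rfftfreq(nwin, d=1.0 / sample_rate)
    fsel = slice(None)
    if spec.freq_range is not None:
        keep = (freqs >= spec.freq_range[0]) & (freqs <= spec.freq_range[1])
        fsel = np.flatnonzero(keep)
    n_out = len(freqs) if isinstance(fsel, slice) else len(fsel)
    power = np.empty((len(starts), n_out))
    # one-sided PSD scaling; interior bins doubled
    scale = np.full(len(freqs), 2.0 / sample_rate)
    scale[0] = 1.0 / sample_rate
    if nwin % 2 == 0:
        scale[-1] = 1.0 / sample_rate
    chunk = 4096
    windows = np.lib.stride_tricks.sliding_window_view(x, nwin)[::step]
    for i0 in range(0, len(starts), chunk):
        seg = windows[i0 : i0 + chunk]  # (m, nwin)
        spec_k = rfft(seg[None, :, :] * tapers[:, None, :], axis=-1)  # (K, m, nf)
        p = (np.abs(spec_k) ** 2).mean(axis=0) * scale  # mean over tapers
        power[i0 : i0 + chunk] = p[:, fsel] if not isinstance(fsel, slice) else p
    t_centers = (starts + (nwin - 1) / 2.0) / sample_rate
    out_freqs = freqs if isinstance(fsel, slice) else freqs[fsel]
    return t_centers, out_freqs, power


def zscore_spectrogram(
    power: np.ndarray, baseline_mask: np.ndarray, min_baseline_windows: int = 100
) -> np.ndarray:
    """Z-score each frequency bin against baseline (immobility) windows."""
    power = np.asarray(power, dtype=float)
    mask = np.asarray(baseline_mask, dtype=bool)
    if mask.shape[0] != power.shape[0]:
        raise ValueError("baseline mask length must match the window axis")
    if int(mask.sum()) < min_baseline_windows:
        raise ValueError(
            f"baseline has {int(mask.sum())} windows; need >= {min_baseline_windows}"
        )
    base = power[mask]
    mu = base.mean(axis=0)
    sd = base.std(axis=0)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValueError(f"zero baseline variance in frequency bin(s) {bad.tolist()}")
    return (power - mu) / sd


def sg_power_during_swrs(
    z: np.ndarray,
    t_centers: np.ndarray,
    freqs: np.ndarray,
    events: list[RippleEvent],
    sg_band: tuple[float, float] = SG_BAND,
    window: tuple[float, float] = SG_WINDOW,
) -> float:
    """Mean z-scored slow-gamma power in the post-onset window, over events.

    Window membership is by window-centre convention and the (0, 100] ms
    window is right-closed; frequency bins with centres inside ``sg_band``
    (inclusive) enter the mean. Events whose post-onset window contains no
    spectrogram centre are skipped; if none remain an error is raised.
    """
    if not events:
        raise ValueError("no events")
    fsel = (freqs >= sg_band[0]) & (freqs <= sg_band[1])
    if not np.any(fsel):
        raise ValueError(f"no frequency bins inside {sg_band}")
    per_event = []
    for ev in events:
        t0 = ev.trigger_s + window[0]
        t1 = ev.trigger_s + window[1]
        wsel = (t_centers > t0) & (t_centers <= t1)
        if not np.any(wsel):
            continue
        per_event.append(float(np.mean(z[np.ix_(wsel, fsel)])))
    if not per_event:
        raise ValueError("no spectrogram window falls in any post-event range")
    return float(np.mean(per_event))


def peri_event_spectrogram(
    z: np.ndarray,
    t_centers: np.ndarray,
    freqs: np.ndarray,
    events: list[RippleEvent],
    rel_range: tuple[float, float] = (-0.2, 0.3),
) -> PeriEventSpectrogram:
    """Average z-scored spectrogram triggered on event onsets."""
    if not events:
        raise ValueError("no events")
    step = float(np.median(np.diff(t_centers)))
    n_rel = int(round((rel_range[1] - rel_range[0]) / step)) + 1
    rel = rel_range[0] + step * np.arange(n_rel)
    acc = np.zeros((len(rel), len(freqs)))
    n = 0
    for ev in events:
        idx = np.searchsorted(t_centers, ev.trigger_s + rel)
        if idx[0] <= 0 or idx[-1] >= len(t_centers):
            continue
        acc += z[idx]
        n += 1
    if n == 0:
        raise ValueError("no event fully covered by the spectrogram")
    return PeriEventSpectrogram(rel_time=rel, freq=freqs, z=acc / n, n_events=n)


def aggregate_feature(per_site: pd.DataFrame, min_sessions: int = 1) -> pd.DataFrame:
    """Aggregate per-site feature values to one number per mouse and region.

    ``per_site`` columns: mouse_id, session_index, site_id, region, value.
    Member sites of a region are averaged within a session, sessions are then
    averaged with equal weight (controls for estrous-cycle effects across
    days). A mouse with no site in a region gets NaN there (the missing
    sentinel) and is retained for other regions; it is never imputed as 0.
    """
    required = {"mouse_id", "session_index", "region", "value"}
    if not required.issubset(per_site.columns):
        raise ValueError(f"per_site must have columns {sorted(required)}")
    per_session = (
        per_site.dropna(subset=["value"])
        .groupby(["mouse_id", "region", "session_index"], sort=True)["value"]
        .mean()
    )
    per_mouse = per_session.groupby(["mouse_id", "region"]).mean()
    table = per_mouse.unstack("region")
    return table
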