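"""Behavioral metrics for the Morris water maze (MWM) and active place
avoidance (APA) tasks.

MWM trials live in the pool frame (cm, pool centre at the origin); APA
trials are tracked in the rotating-arena frame and converted to the room
frame with the known rotation rate (1 rpm = 6 deg/s) before any shock-zone
geometry is applied. The shock zone is a 60 degree sector fixed in the room.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MWMTrial",
    "APATrial",
    "ShockZone",
    "mwm_metric_row",
    "apa_metric_row",
    "mwm_daily_latency",
    "latency_slope",
    "overnight_change",
    "probe_quadrant_time",
    "probe_target_crossings",
    "probe_distance_auc",
    "apa_room_frame",
    "apa_entrances",
    "apa_entrance_intervals",
    "apa_latency_first_entrance",
    "apa_path_length",
    "apa_opposite_quadrant_time",
    "apa_bout_distance",
    "apa_pseudoshocks_per_entrance",
]

MWM_TRIAL_CAP_S = 60.0
APA_TRIAL_CAP_S = 600.0


@dataclass
class MWMTrial:
    """One water-maze trial: 122 cm pool, 14x14 cm platform, 60 s cap."""

    day: int
    trial_index: int
    kind: str  # HIDDEN | PROBE | VISIBLE
    track: np.ndarray  # (n, 3): t_s, x_cm, y_cm in pool frame
    escape_latency_s: float = math.nan
    platform_center: tuple[float, float] = (0.0, 0.0)
    platform_half_width: float = 7.0
    pool_radius: float = 61.0


@dataclass
class APATrial:
    """One place-avoidance trial: 40 cm arena rotating at 1 rpm, 10 min."""

    day: int
    kind: str  # HABITUATION | TRAIN | PROBE_REINSTATE
    track_arena: np.ndarray  # (n, 3): t_s, x_cm, y_cm in rotating-arena frame
    arena_radius: float = 20.0
    rotation_deg_s: float = 6.0
    zone_center_deg_room: float = 0.0
    zone_width_deg: float = 60.0
    shock_times: list = field(default_factory=list)
    duration_s: float = APA_TRIAL_CAP_S


@dataclass(frozen=True)
class ShockZone:
    center_deg: float
    width_deg: float = 60.0

    def contains(self, angle_deg: np.ndarray) -> np.ndarray:
        d = _wrap_deg(np.asarray(angle_deg, dtype=float) - self.center_deg)
        # half-open sector [-w/2, +w/2): no double counting on the boundary
        return (d >= -self.width_deg / 2) & (d < self.width_deg / 2)


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles to [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------- MWM ----


def mwm_metric_row(trials: list[MWMTrial]) -> dict:
    """All composite-set MWM metrics for one mouse's trial list."""
    days = sorted({t.day for t in trials if t.kind == "HIDDEN"})
    daily = [(d, mwm_daily_latency(trials, d)) for d in days]
    probes = sorted((t for t in trials if t.kind == "PROBE"),
                    key=lambda t: (t.day, t.trial_index))
    out = {
        "mwm_latency_slope_d1_2": latency_slope(daily, (1, 2)),
        "mwm_latency_slope_d1_3": latency_slope(daily, (1, 3)),
        "mwm_latency_d3": dict(daily)[3],
        "mwm_overnight_change_d1_2": overnight_change(trials, (1, 2)),
    }
    for i, probe in enumerate(probes[:2], start=1):
        out[f"mwm_probe{i}_quadrant_pct"] = probe_quadrant_time(probe)
        out[f"mwm_probe{i}_auc"] = probe_distance_auc(probe)
    if probes:
        out["mwm_probe1_crossings"] = probe_target_crossings(probes[0])
    return out


def apa_metric_row(trials: list[APATrial]) -> dict:
    """All composite-set APA metrics for one mouse's trial list."""
    zone = ShockZone(trials[0].zone_center_deg_room, trials[0].zone_width_deg)
    by_day = {t.day: t for t in trials}
    day2, day3 = by_day[2], by_day.get(3)
    room2 = apa_room_frame(day2.track_arena, day2.rotation_deg_s)
    out = {
        "apa_entrances_d2": apa_entrances(room2, zone),
        "apa_latency_first_entrance_d2": apa_latency_first_entrance(
            room2, zone, day2.duration_s),
        "apa_path_length_d2": apa_path_length(day2.track_arena),
        "apa_opposite_quadrant_pct_d2": apa_opposite_quadrant_time(room2, zone),
        "apa_bout_distance_d2": apa_bout_distance(day2.track_arena, zone,
                                                  day2.rotation_deg_s),
    }
    if day3 is not None:
        out["apa_bout_distance_d3"] = apa_bout_distance(day3.track_arena, zone,
                                                        day3.rotation_deg_s)
    probe = next((t for t in trials if t.kind == "PROBE_REINSTATE"), None)
    if probe is not None:
        room_p = apa_room_frame(probe.track_arena, probe.rotation_deg_s)
        out["apa_pseudoshocks_per_entrance"] = apa_pseudoshocks_per_entrance(room_p, zone)
    return out


def mwm_daily_latency(trials: list[MWMTrial], day: int) -> float:
    """Mean escape latency of a day's hidden trials (one value per day)."""
    lats = [t.escape_latency_s for t in trials if t.day == day and t.kind == "HIDDEN"]
    if not lats:
        raise ValueError(f"no hidden trials on day {day}")
    if len(lats) == 1:
        log.warning("day %d has a single hidden trial; daily latency = that trial", day)
    return float(np.mean(lats))


def latency_slope(daily: list[tuple[int, float]], day_range: tuple[int, int]) -> float:
    """Least-squares slope of daily escape latency over an inclusive day range (s/day)."""
    d1, dk = day_range
    pts = [(d, v) for d, v in daily if d1 <= d <= dk]
    if len(pts) < 2:
        raise ValueError(f"need >= 2 days in range {day_range}")
    days = np.array([p[0] for p in pts], dtype=float)
    vals = np.array([p[1] for p in pts], dtype=float)
    return float(np.polyfit(days, vals, 1)[0])


def overnight_change(trials: list[MWMTrial], day_pair: tuple[int, int]) -> float:
    """Latency(first trial of day d+1) - latency(last trial of day d).

    Negative values mean the animal improved overnight (19 h of rest between
    the two trials).
    """
    d0, d1 = day_pair
    day0 = sorted(
        (t for t in trials if t.day == d0 and t.kind == "HIDDEN"), key=lambda t: t.trial_index
    )
    day1 = sorted(
        (t for t in trials if t.day == d1 and t.kind == "HIDDEN"), key=lambda t: t.trial_index
    )
    if not day0 or not day1:
        raise ValueError(f"missing hidden trials for day pair {day_pair}")
    return float(day1[0].escape_latency_s - day0[-1].escape_latency_s)


def _quadrant_index(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pool quadrant by half-open angular convention: [0,90), [90,180), ..."""
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    return (ang // 90.0).astype(int)


def probe_quadrant_time(trial: MWMTrial, platform_center: tuple[float, float] | None = None) -> float:
    """Percent of probe-trial frames spent in the quadrant of the platform."""
    track = np.asarray(trial.track, dtype=float)
    if track.size == 0:
        raise ValueError("empty track")
    cx, cy = platform_center if platform_center is not None else trial.platform_center
    target_q = int(_quadrant_index(np.array([cx]), np.array([cy]))[0])
    q = _quadrant_index(track[:, 1], track[:, 2])
    return 100.0 * float(np.mean(q == target_q))


def probe_target_crossings(
    trial: MWMTrial,
    platform_center: tuple[float, float] | None = None,
    platform_half_width: float | None = None,
) -> int:
    """Entries of the tracked point into the 14x14 cm former platform square."""
    track = np.asarray(trial.track, dtype=float)
    cx, cy = platform_center if platform_center is not None else trial.platform_center
    hw = platform_half_width if platform_half_width is not None else trial.platform_half_width
    inside = (np.abs(track[:, 1] - cx) <= hw) & (np.abs(track[:, 2] - cy) <= hw)
    if inside.size == 0:
        return 0
    entries = int(np.sum(inside[1:] & ~inside[:-1])) + int(inside[0])
    return entries


def probe_distance_auc(
    trial: MWMTrial,
    platform_center: tuple[float, float] | None = None,
    horizon_s: float = 5.0,
) -> float:
    """Trapezoid area under the distance-to-platform curve over [0, horizon] (cm*s)."""
    track = np.asarray(trial.track, dtype=float)
    cx, cy = platform_center if platform_center is not None else trial.platform_center
    t = track[:, 0] - track[0, 0]
    if t[-1] < horizon_s:
        raise ValueError(f"track covers {t[-1]:.2f} s < horizon {horizon_s} s")
    sel = t <= horizon_s
    d = np.hypot(track[sel, 1] - cx, track[sel, 2] - cy)
    return float(np.trapezoid(d, t[sel]))


# ---------------------------------------------------------------- APA ----


def apa_room_frame(track_arena: np.ndarray, rotation_deg_s: float) -> np.ndarray:
    """Convert an arena-frame track to (t, room angle deg, radius cm).

    The arena rotates at ``rotation_deg_s``; a point fixed on the arena
    advances through the room at that rate: angle_room = angle_arena +
    rotation * t (mod 360).
    """
    track = np.asarray(track_arena, dtype=float)
    t = track[:, 0]
    ang_arena = np.degrees(np.arctan2(track[:, 2], track[:, 1]))
    radius = np.hypot(track[:, 1], track[:, 2])
    ang_room = (ang_arena + rotation_deg_s * t) % 360.0
    return np.column_stack([t, ang_room, radius])


def apa_entrance_intervals(
    room: np.ndarray, zone: ShockZone, hysteresis_s: float = 0.5
) -> list[tuple[float, float]]:
    """(entry_time, exit_time) pairs for shock-zone visits.

    A new entrance requires the animal to have been continuously outside
    the zone for at least ``hysteresis_s`` since the last exit, so boundary
    jitter at the frame rate is not counted repeatedly.
    """
    t = room[:, 0]
    inside = zone.contains(room[:, 1])
    visits: list[tuple[float, float]] = []
    # starting inside is not an entrance (the animal was placed there); only
    # outside -> inside transitions count
    state_inside = False
    entry_t = None
    last_exit = -math.inf
    first = 0
    while first < len(t) and inside[first]:  # skip an initial inside period
        first += 1
    for i in range(first + 1, len(t)):
        if not state_inside and inside[i]:
            if t[i] - last_exit >= hysteresis_s or not visits:
                entry_t = t[i]
                state_inside = True
            else:  # re-entry within hysteresis: extend the previous visit
                entry_t = visits.pop()[0]
                state_inside = True
        elif state_inside and not inside[i]:
            visits.append((entry_t, t[i]))
            last_exit = t[i]
            state_inside = False
    if state_inside:
        visits.append((entry_t, t[-1]))
    return visits


def apa_entrances(room: np.ndarray, zone: ShockZone, hysteresis_s: float = 0.5) -> int:
    """Number of entrances into the room-fixed shock zone."""
    return len(apa_entrance_intervals(room, zone, hysteresis_s))


def apa_latency_first_entrance(
    room: np.ndarray, zone: ShockZone, duration_s: float = APA_TRIAL_CAP_S
) -> float:
    """Time of the first entrance, capped at trial duration when none occurs."""
    inside = zone.contains(room[:, 1])
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        return float(duration_s)
    return float(room[idx[0], 0])


def apa_path_length(track_arena: np.ndarray) -> float:
    """Path length in the rotating-arena frame (cm): movement the animal made."""
    track = np.asarray(track_arena, dtype=float)
    if track.shape[0] < 2:
        raise ValueError("need >= 2 frames")
    return float(np.sum(np.hypot(np.diff(track[:, 1]), np.diff(track[:, 2]))))


def apa_opposite_quadrant_time(room: np.ndarray, zone: ShockZone) -> float:
    """Percent time in the 90-degree sector antipodal to the zone centre."""
    opposite = ShockZone(center_deg=zone.center_deg + 180.0, width_deg=90.0)
    inside = opposite.contains(room[:, 1])
    return 100.0 * float(np.mean(inside))


def _arc_distance_from_zone(angle_deg: np.ndarray, radius_cm: float, zone: ShockZone) -> np.ndarray:
    """Arc distance (cm) from the nearest zone boundary, 0 inside the zone."""
    d = np.abs(_wrap_deg(np.asarray(angle_deg) - zone.center_deg))
    deg_out = np.maximum(0.0, d - zone.width_deg / 2)
    return np.radians(deg_out) * radius_cm


def apa_bout_distance(
    track_arena: np.ndarray,
    zone: ShockZone,
    rotation_deg_s: float = 6.0,
    speed_threshold_cm_s: float = 2.0,
    min_bout_s: float = 0.5,
    min_gap_s: float = 1.0,
    cumulative: bool = False,
) -> float:
    """Mean per-bout net change in arc distance from the shock zone (cm).

    Movement bouts are runs of arena-frame speed above
    ``speed_threshold_cm_s`` lasting at least ``min_bout_s``; pauses shorter
    than ``min_gap_s`` do not split a bout. For each bout the room-frame arc
    distance (at the bout's mean radius) from the nearest zone boundary is
    compared between bout end and bout start; positive = moved away from the
    zone. ``cumulative=True`` sums absolute step-wise changes instead.
    Returns NaN (the missing sentinel) when there is no bout.
    """
    track = np.asarray(track_arena, dtype=float)
    if track.shape[0] < 2:
        return math.nan
    t = track[:, 0]
    dt = np.median(np.diff(t))
    speed = np.hypot(np.diff(track[:, 1]), np.diff(track[:, 2])) / np.diff(t)
    speed = np.append(speed, speed[-1])
    moving = speed > speed_threshold_cm_s
    bouts = _bouts(moving, t, min_bout_s, min_gap_s)
    if not bouts:
        return math.nan
    room = apa_room_frame(track, rotation_deg_s)
    per_bout = []
    for i0, i1 in bouts:
        radius = float(np.mean(room[i0 : i1 + 1, 2]))
        dist = _arc_distance_from_zone(room[i0 : i1 + 1, 1], radius, zone)
        if cumulative:
            per_bout.append(float(np.sum(np.abs(np.diff(dist)))))
        else:
            per_bout.append(float(dist[-1] - dist[0]))
    return float(np.mean(per_bout))


def _bouts(moving: np.ndarray, t: np.ndarray, min_bout_s: float, min_gap_s: float) -> list[tuple[int, int]]:
    """Index ranges [i0, i1] of movement bouts after gap-merging."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], moving.view(np.int8), [0]))))
    runs = list(zip(idx[0::2], idx[1::2] - 1))
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if t[s] - t[merged[-1][1]] < min_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if t[e] - t[s] >= min_bout_s]


def apa_pseudoshocks_per_entrance(
    room: np.ndarray,
    zone: ShockZone,
    shock_period_s: float = 1.5,
    hysteresis_s: float = 0.5,
) -> float:
    """Pseudoshocks per entrance on a probe trial.

    The shock schedule is simulated: a shock at each entrance, repeating
    every ``shock_period_s`` while the animal stays inside the zone. Returns
    total pseudoshocks / entrances, or NaN when there is no entrance.
    """
    visits = apa_entrance_intervals(room, zone, hysteresis_s)
    if not visits:
        return math.nan
    total = 0
    for entry, exit_ in visits:
        # shocks at entry, entry+T, ... while strictly inside the visit
        stay = exit_ - entry
        total += 1 + int(math.floor((stay - 1e-9) / shock_period_s))
    return total / len(visits)
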