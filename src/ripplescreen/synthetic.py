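"""Synthetic sessions, trajectories, and cohorts with known ground truth.

The LFP generator plants Gaussian-enveloped ripple-band tones (with a
coincident negative sharp wave and a post-onset slow-gamma burst) on top of
1/f background noise, during immobility only, at a Poisson rate. The cohort
generator plants linear feature->metric relationships at a stated population
R^2 so that recovery by the full pipeline can be scored exactly.

All generators are seed-deterministic: the same parameters and seed give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import APATrial, MWMTrial, ShockZone
from .preprocess import FilterKind, FilterSpec, IntervalSet, bandpass_filter
from .session_io import AgeGroup, ElectrodeSite, Genotype, LFPSession, Region
from . import cohort_stats as cs

__all__ = [
    "LFPSimParams",
    "CohortSimParams",
    "GroundTruth",
    "CohortGroundTruth",
    "default_montage",
    "simulate_lfp_session",
    "simulate_mwm_trials",
    "simulate_apa_trials",
    "simulate_cohort",
]


def default_montage(n_shanks: int = 4, sites_per_shank: int = 8) -> list[ElectrodeSite]:
    """Silicon-array montage: shanks of 8 sites spanning CC to DG.

    Depth order per shank mirrors a dorsal-hippocampus insertion: corpus
    callosum above CA1, then the CA1 pyramidal layer, stratum radiatum,
    CA3, and dentate gyrus.
    """
    depth_regions = [
        Region.CORPUS_CALLOSUM,
        Region.CA1_PYR,
        Region.CA1_SR,
        Region.CA1_SR,
        Region.CA3,
        Region.CA3,
        Region.DG,
        Region.DG,
    ]
    sites = []
    for sh in range(n_shanks):
        for d in range(sites_per_shank):
            sites.append(
                ElectrodeSite(
                    site_id=f"s{sh}d{d}",
                    shank_index=sh,
                    depth_index=d,
                    region=depth_regions[d % len(depth_regions)],
                )
            )
    return sites


#: compact montage used for focused single-feature simulations
MINIMAL_MONTAGE = [
    ElectrodeSite("s0d1", 0, 1, Region.CA1_PYR),
    ElectrodeSite("s0d2", 0, 2, Region.CA1_SR),
    ElectrodeSite("s0d4", 0, 4, Region.CA3),
    ElectrodeSite("s0d6", 0, 6, Region.DG),
]


@dataclass(frozen=True)
class LFPSimParams:
    """Parameters of one synthetic home-cage session.

    Amplitudes are expressed in SDs of the band-filtered background noise
    (``ripple_amp_sd``, ``sg_mod_amp``), so detection thresholds in SD units
    see a scale-free planted signal. The immobility schedule is a repeating
    (mobile_s, immobile_s) block pattern that must tile the session exactly.
    """

    seed: int = 0
    duration_s: float = 3600.0
    sample_rate: float = 1000.0
    noise_exponent: float = 1.0
    noise_sd_uv: float = 15.0
    ripple_rate_hz: float = 0.2
    ripple_amp_sd: float = 8.0
    ripple_freq_range: tuple[float, float] = (150.0, 220.0)
    ripple_env_sigma_s: float = 0.02
    sharp_wave_amp_uv: float = 100.0
    sg_mod_amp: float = 3.0
    sg_freq_hz: float = 40.0
    sg_window_s: float = 0.1
    immobility_schedule: tuple[tuple[float, float], ...] = ((60.0, 240.0),)
    min_event_separation_s: float = 0.3
    edge_margin_s: float = 0.2
    mouse_id: str = "sim"
    genotype: Genotype = Genotype.E4
    age_group: AgeGroup = AgeGroup.OLD
    session_index: int = 1
    montage: tuple[ElectrodeSite, ...] | None = None


@dataclass
class GroundTruth:
    """Planted facts of one synthetic session."""

    event_times: np.ndarray  # planted event times, s (one env sigma before peak)
    event_centers: np.ndarray
    event_freqs: np.ndarray
    sg_mod_amp: float
    immobile_blocks: IntervalSet  # full immobile blocks of the schedule
    qualified_immobility: IntervalSet  # blocks trimmed by the 30 s qualification
    ripple_band_sd_uv: float
    sg_band_sd_uv: float


def _schedule_blocks(params: LFPSimParams) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """(mobile, immobile) block lists tiling the session; errors on mismatch."""
    pattern = params.immobility_schedule
    cycle = sum(m + i for m, i in pattern)
    n_cycles = params.duration_s / cycle
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        raise ValueError(
            f"immobility schedule (cycle {cycle} s) does not tile duration {params.duration_s} s"
        )
    mobile, immobile = [], []
    t = 0.0
    for _ in range(int(round(n_cycles))):
        for m, i in pattern:
            if m > 0:
                mobile.append((t, t + m))
            t += m
            if i > 0:
                immobile.append((t, t + i))
            t += i
    return mobile, immobile


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent amplitude-shaped Gaussian noise, normalized to sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    return x * (sd / np.std(x))


def _band_sd(noise: np.ndarray, band: tuple[float, float], fs: float) -> float:
    spec = FilterSpec(FilterKind.BUTTER_BANDPASS, band[0], band[1], 4)
    return float(np.std(bandpass_filter(noise, spec, fs)))


def _plant_positions(rng: np.random.Generator, blocks: list[tuple[float, float]],
                     rate: float, qualify_s: float, margin: float, min_sep: float) -> np.ndarray:
    """Poisson event onsets inside qualified immobility, away from edges.

    The count per block is Poisson(rate x usable length); a minimum
    separation is then imposed by a spacing transform that preserves the
    count, so the planted rate is exactly the nominal rate.
    """
    times: list[float] = []
    for start, end in blocks:
        lo = start + qualify_s + margin
        hi = end - margin
        if hi <= lo:
            continue
        length = hi - lo
        n = rng.poisson(rate * length)
        if n == 0:
            continue
        slack = length - n * min_sep
        if slack <= 0:  # too dense for the separation rule: space evenly
            times.extend(lo + (np.arange(n) + 0.5) * length / n)
            continue
        gaps = np.sort(rng.uniform(0.0, slack, size=n))
        times.extend(lo + gaps + np.arange(n) * min_sep)
    return np.asarray(times)


def simulate_lfp_session(params: LFPSimParams) -> tuple[LFPSession, GroundTruth]:
    """Generate one synthetic session and its ground truth.

    Per planted event: a ripple-band tone (Gaussian envelope,
    ``ripple_env_sigma_s``) on every CA1 pyramidal site, a negative sharp
    wave on CA1 stratum radiatum, and a slow-gamma burst of amplitude
    ``sg_mod_amp`` (in SG-band background SDs) on CA3/CA1-sr/DG confined to
    the 0-100 ms post-onset window. The position track realizes the
    immobility schedule at 30 Hz.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n = int(round(params.duration_s * fs))
    sites = list(params.montage) if params.montage is not None else default_montage()
    mobile, immobile = _schedule_blocks(params)

    signals = np.empty((len(sites), n))
    for i in range(len(sites)):
        signals[i] = _one_over_f_noise(rng, n, fs, params.noise_exponent, params.noise_sd_uv)

    # band SDs of the background measured on representative sites
    ripple_band = (150.0, 250.0)
    det_idx = next((i for i, s in enumerate(sites) if s.region is Region.CA1_PYR), 0)
    sg_idx = next((i for i, s in enumerate(sites) if s.region is Region.CA3), det_idx)
    sd_ripple = _band_sd(signals[det_idx], ripple_band, fs)
    sd_sg = _band_sd(signals[sg_idx], (30.0, 50.0), fs)

    onsets = _plant_positions(
        rng, immobile, params.ripple_rate_hz, 30.0, params.edge_margin_s,
        params.min_event_separation_s,
    )
    # planted event time = one envelope sigma before the burst peak (the
    # e^-1/2 rise point, roughly where a 5 SD detector first sees the burst)
    centers = onsets + params.ripple_env_sigma_s
    freqs = rng.uniform(*params.ripple_freq_range, size=len(onsets))
    phases = rng.uniform(0, 2 * np.pi, size=len(onsets))
    sg_phases = rng.uniform(0, 2 * np.pi, size=len(onsets))

    pyr_rows = [i for i, s in enumerate(sites) if s.region is Region.CA1_PYR]
    sr_rows = [i for i, s in enumerate(sites) if s.region is Region.CA1_SR]
    sg_rows = [i for i, s in enumerate(sites) if s.region in (Region.CA3, Region.CA1_SR, Region.DG)]

    sig_e = params.ripple_env_sigma_s
    half = int(round(4 * sig_e * fs))
    tloc = np.arange(-half, half + 1) / fs
    sw_sigma = 0.015
    sw_half = int(round(4 * sw_sigma * fs))
    tsw = np.arange(-sw_half, sw_half + 1) / fs
    sw_wave = -params.sharp_wave_amp_uv * np.exp(-(tsw**2) / (2 * sw_sigma**2))
    n_sg = int(round(params.sg_window_s * fs))
    u = np.arange(n_sg) / n_sg
    sg_env = np.sin(np.pi * u) ** 2  # Hann over the 0-100 ms window

    for k, (c, f0, ph, ph_sg) in enumerate(zip(centers, freqs, phases, sg_phases)):
        ci = int(round(c * fs))
        burst = (params.ripple_amp_sd * sd_ripple) * np.exp(-(tloc**2) / (2 * sig_e**2)) * np.cos(
            2 * np.pi * f0 * tloc + ph
        )
        _add(signals, pyr_rows, burst, ci - half)
        _add(signals, sr_rows, sw_wave, ci - sw_half)
        if params.sg_mod_amp > 0:
            oi = int(round(onsets[k] * fs))
            tsg = np.arange(n_sg) / fs
            sgb = (params.sg_mod_amp * sd_sg) * sg_env * np.cos(2 * np.pi * params.sg_freq_hz * tsg + ph_sg)
            _add(signals, sg_rows, sgb, oi)

    position = _home_cage_track(rng, params.duration_s, mobile)

    session = LFPSession(
        mouse_id=params.mouse_id,
        genotype=params.genotype,
        age_group=params.age_group,
        session_index=params.session_index,
        sample_rate=fs,
        signals=signals,
        sites=sites,
        position=position,
    )
    truth = GroundTruth(
        event_times=onsets,
        event_centers=centers,
        event_freqs=freqs,
        sg_mod_amp=params.sg_mod_amp,
        immobile_blocks=IntervalSet(immobile),
        qualified_immobility=IntervalSet(
            [(s + 30.0, e) for s, e in immobile if e - s >= 30.0]
        ),
        ripple_band_sd_uv=sd_ripple,
        sg_band_sd_uv=sd_sg,
    )
    return session, truth


def _add(signals: np.ndarray, rows: list[int], wave: np.ndarray, start: int) -> None:
    n = signals.shape[1]
    w0 = max(0, -start)
    w1 = min(len(wave), n - start)
    if w1 <= w0:
        return
    for r in rows:
        signals[r, start + w0 : start + w1] += wave[w0:w1]


def _home_cage_track(rng: np.random.Generator, duration_s: float,
                     mobile_blocks: list[tuple[float, float]], fps: float = 30.0,
                     box: tuple[float, float] = (30.0, 15.0)) -> np.ndarray:
    """30 Hz track: smooth walk in a home-cage box during mobile blocks,
    near-zero jitter otherwise."""
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    mobile = np.zeros(n, dtype=bool)
    for s, e in mobile_blocks:
        mobile[(t >= s) & (t < e)] = True
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = box[0] / 2, box[1] / 2
    heading = rng.uniform(0, 2 * np.pi)
    speed = 5.0  # cm/s while mobile
    for i in range(1, n):
        if mobile[i]:
            heading += rng.normal(0, 0.3)
            dx = speed / fps * math.cos(heading)
            dy = speed / fps * math.sin(heading)
            nx, ny = x[i - 1] + dx, y[i - 1] + dy
            if not (0 < nx < box[0]):
                heading = math.pi - heading
                nx = np.clip(nx, 0.0, box[0])
            if not (0 < ny < box[1]):
                heading = -heading
                ny = np.clip(ny, 0.0, box[1])
            x[i], y[i] = nx, ny
        else:
            x[i] = x[i - 1] + rng.normal(0, 0.003)
            y[i] = y[i - 1] + rng.normal(0, 0.003)
    return np.column_stack([t, x, y])


# ------------------------------------------------------------ behavior ----


def simulate_mwm_trials(
    skill: float,
    seed: int,
    n_days: int = 5,
    trials_per_day: int = 4,
    n_probes: int = 3,
    pool_radius: float = 61.0,
    platform_center: tuple[float, float] = (30.0, 30.0),
    fps: float = 30.0,
) -> list[MWMTrial]:
    """Water-maze trials from a biased random swim.

    ``skill`` in [0, 1] scales both the homing bias and its growth across
    days, so expected escape latency decreases in skill and across days;
    probe paths concentrate near the platform in proportion to skill
    (skill 0 is an unbiased wall-reflecting swim: ~25% per quadrant).
    """
    if not (0.0 <= skill <= 1.0):
        raise ValueError("skill must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    trials: list[MWMTrial] = []
    for day in range(1, n_days + 1):
        # naive on day 1 regardless of ability; homing bias grows with days
        learn = (0.1 + 0.9 * (day - 1) / max(n_days - 1, 1)) * skill
        for ti in range(1, trials_per_day + 1):
            track, latency = _swim(rng, learn, pool_radius, platform_center, fps,
                                   cap_s=60.0, stop_at_platform=True)
            trials.append(
                MWMTrial(day=day, trial_index=ti, kind="HIDDEN", track=track,
                         escape_latency_s=latency, platform_center=platform_center,
                         pool_radius=pool_radius)
            )
    for p in range(1, n_probes + 1):
        track, _ = _swim(rng, skill * 0.8, pool_radius, platform_center, fps,
                         cap_s=60.0, stop_at_platform=False)
        trials.append(
            MWMTrial(day=n_days + p, trial_index=p, kind="PROBE", track=track,
                     escape_latency_s=60.0, platform_center=platform_center,
                     pool_radius=pool_radius)
        )
    return trials


def _swim(rng: np.random.Generator, bias: float, pool_radius: float,
          platform: tuple[float, float], fps: float, cap_s: float,
          stop_at_platform: bool, speed: float = 18.0,
          platform_half_width: float = 7.0) -> tuple[np.ndarray, float]:
    n = int(cap_s * fps)
    start_ang = rng.uniform(0, 2 * np.pi)
    px, py = platform
    x = [0.95 * pool_radius * math.cos(start_ang)]
    y = [0.95 * pool_radius * math.sin(start_ang)]
    heading = rng.uniform(0, 2 * np.pi)
    latency = cap_s
    ts = [0.0]
    for i in range(1, n):
        goal = math.atan2(py - y[-1], px - x[-1])
        # blend persistent heading with the homing direction
        heading += _wrap_rad(goal - heading) * bias * 0.5 + rng.normal(0, 0.45 * (1 - 0.6 * bias))
        nx = x[-1] + speed / fps * math.cos(heading)
        ny = y[-1] + speed / fps * math.sin(heading)
        r = math.hypot(nx, ny)
        if r > pool_radius:
            nx *= pool_radius / r
            ny *= pool_radius / r
            heading += math.pi / 2 * rng.choice([-1.0, 1.0])
        x.append(nx)
        y.append(ny)
        ts.append(i / fps)
        if stop_at_platform and abs(nx - px) <= platform_half_width and abs(ny - py) <= platform_half_width:
            latency = i / fps
            break
    return np.column_stack([ts, x, y]), latency


def _wrap_rad(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def simulate_apa_trials(
    avoidance: float,
    seed: int,
    n_days: int = 4,
    duration_s: float = 600.0,
    arena_radius: float = 20.0,
    rotation_deg_s: float = 6.0,
    zone_center_deg: float = 0.0,
    fps: float = 30.0,
) -> list[APATrial]:
    """Place-avoidance trials from a room-frame walk with zone repulsion.

    The animal's room-frame angle performs a random walk; with probability
    ``avoidance`` an excursion inside the protective margin around the
    room-fixed shock zone is reflected back out, so entrance counts decrease
    monotonically in ``avoidance`` (1.0 gives zero entrances for almost all
    seeds). Tracks are returned in the rotating-arena frame, as tracked.
    """
    if not (0.0 <= avoidance <= 1.0):
        raise ValueError("avoidance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    trials: list[APATrial] = []
    zone = ShockZone(zone_center_deg, 60.0)
    n = int(duration_s * fps)
    for day in range(1, n_days + 1):
        theta = rng.uniform(60.0, 300.0)  # room angle, start away from the zone
        radius = 0.7 * arena_radius
        th = np.empty(n)
        rr = np.empty(n)
        committed = False
        prev_d = _wrap_deg_scalar(theta - zone_center_deg)
        for i in range(n):
            # passive drift with the rotating arena (counteracted in
            # proportion to avoidance) plus exploratory jitter
            theta += (1.0 - avoidance) * rotation_deg_s / fps
            theta += rng.normal(0, 6.0 / math.sqrt(fps))
            radius = float(np.clip(radius + rng.normal(0, 0.5 / math.sqrt(fps)), 3.0, arena_radius - 1.0))
            d = _wrap_deg_scalar(theta - zone_center_deg)
            # each approach to the zone boundary is either actively avoided
            # (hold position just outside, counter-rotating) or swept through
            # with a quick shock-driven escape
            if -48.0 < d <= -31.0 and prev_d <= -48.0:
                committed = rng.uniform() < avoidance
            if committed:
                if d > -31.0:
                    theta = zone_center_deg - 31.0
                    d = -31.0
                elif d <= -48.0:
                    committed = False
            elif abs(d) < 30.0:
                theta += 2.0  # fleeing forward out of the zone
                d = _wrap_deg_scalar(theta - zone_center_deg)
            prev_d = d
            th[i] = theta
            rr[i] = radius
        t = np.arange(n) / fps
        ang_arena = np.radians(th - rotation_deg_s * t)
        track = np.column_stack([t, rr * np.cos(ang_arena), rr * np.sin(ang_arena)])
        trials.append(
            APATrial(day=day, kind="TRAIN", track_arena=track, arena_radius=arena_radius,
                     rotation_deg_s=rotation_deg_s, zone_center_deg_room=zone_center_deg,
                     duration_s=duration_s)
        )
    return trials


def _wrap_deg_scalar(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


# -------------------------------------------------------------- cohort ----


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort-level generator: features and metrics with planted effects.

    ``effect_r2_abundance`` / ``effect_r2_sg`` are the target population R^2
    between the z-scored feature and the corresponding composite score
    (defaults are the effect sizes the screening study design anticipates:
    0.51 for abundance->learning at n=16 and 0.77 for CA3 SG->precision).
    """

    seed: int = 0
    n_mice: int = 16
    cohort_label: str = "SCREEN"
    task: str = "MWM"
    effect_r2_abundance: float = 0.51
    effect_r2_sg: float = 0.77
    abundance_mean_hz: float = 0.12
    abundance_sd_hz: float = 0.04
    sg_mean_z: float = 1.0
    sg_sd_z: float = 0.5
    metric_noise_sd: float = 1.0
    generate_trajectories: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_r2_abundance < 1.0 and 0.0 <= self.effect_r2_sg < 1.0):
            raise ValueError("R^2 targets must lie in [0, 1)")


@dataclass
class CohortGroundTruth:
    latent_abundance_z: np.ndarray
    latent_sg_z: np.ndarray
    per_metric_r2: dict
    planted_r2_learning: float
    planted_r2_precision: float


#: plausible raw-scale location/spread for each behavioral metric
_METRIC_BASE = {
    "mwm_latency_slope_d1_2": (-6.0, 5.0),
    "mwm_latency_slope_d1_3": (-5.0, 4.0),
    "mwm_latency_d3": (35.0, 12.0),
    "mwm_overnight_change_d1_2": (-5.0, 10.0),
    "mwm_probe1_quadrant_pct": (32.0, 10.0),
    "mwm_probe2_quadrant_pct": (30.0, 10.0),
    "mwm_probe1_crossings": (3.0, 1.5),
    "mwm_probe1_auc": (160.0, 40.0),
    "mwm_probe2_auc": (170.0, 40.0),
    "apa_latency_first_entrance_d2": (120.0, 90.0),
    "apa_path_length_d2": (2500.0, 700.0),
    "apa_opposite_quadrant_pct_d2": (35.0, 12.0),
    "apa_entrances_d2": (12.0, 6.0),
    "apa_bout_distance_d2": (8.0, 5.0),
    "apa_bout_distance_d3": (7.0, 5.0),
}


def _per_metric_r2(target_r2: float, k: int) -> float:
    """Per-metric R^2 such that the k-metric composite hits ``target_r2``.

    The composite averages k equally loaded metrics with independent noise;
    its squared correlation with the latent feature is
    r2 / (r2 + (1 - r2)/k), inverted here for r2.
    """
    if target_r2 == 0:
        return 0.0
    return target_r2 / (k * (1.0 - target_r2) + target_r2)


def simulate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, pd.DataFrame, CohortGroundTruth]:
    """Generate per-mouse SWR features and a behavioral metric table.

    Latent z-scored SWR abundance and CA3 SG power are independent standard
    normals (the two features are uncorrelated in the population). Each
    composite-set metric is a linear function of its designated feature plus
    Gaussian noise, scaled so the *composite* score's population R^2 with
    the feature equals the target; planted slopes follow the field's sign
    conventions (e.g., higher abundance -> shallower latency slope).

    Returns (features, metrics, truth): features has columns
    ``swr_abundance_hz`` and ``sg_z_ca3`` indexed by mouse_id.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_mice
    mice = [f"m{params.cohort_label[:1].lower()}{i:02d}" for i in range(n)]
    ab_z = rng.standard_normal(n)
    sg_z = rng.standard_normal(n)

    features = pd.DataFrame(
        {
            "swr_abundance_hz": params.abundance_mean_hz + params.abundance_sd_hz * ab_z,
            "sg_z_ca3": params.sg_mean_z + params.sg_sd_z * sg_z,
        },
        index=pd.Index(mice, name="mouse_id"),
    )

    if params.task == "MWM":
        learning, precision = cs.MWM_LEARNING_METRICS, cs.MWM_PRECISION_METRICS
    elif params.task == "APA":
        learning, precision = cs.APA_LEARNING_METRICS, cs.APA_PRECISION_METRICS
    else:
        raise ValueError(f"unknown task {params.task!r}")

    r2_l = _per_metric_r2(params.effect_r2_abundance, len(learning))
    r2_p = _per_metric_r2(params.effect_r2_sg, len(precision))
    per_metric_r2 = {}
    metrics = pd.DataFrame(index=features.index)
    for name, latent, r2 in [
        *((m, ab_z, r2_l) for m in learning),
        *((m, sg_z, r2_p) for m in precision),
    ]:
        eps = rng.standard_normal(n)
        good = math.sqrt(r2) * latent + math.sqrt(1.0 - r2) * eps
        sign = -1.0 if cs.DEFAULT_SIGN_MAP[name] is cs.Orientation.LOWER_IS_BETTER else 1.0
        mean, sd = _METRIC_BASE[name]
        metrics[name] = mean + sd * params.metric_noise_sd * sign * good
        per_metric_r2[name] = r2

    truth = CohortGroundTruth(
        latent_abundance_z=ab_z,
        latent_sg_z=sg_z,
        per_metric_r2=per_metric_r2,
        planted_r2_learning=params.effect_r2_abundance,
        planted_r2_precision=params.effect_r2_sg,
    )
    if params.generate_trajectories:
        # latent goodness -> [0, 1] skill via the normal CDF
        from scipy.stats import norm

        trials = {}
        for i, mid in enumerate(mice):
            sub = int(rng.integers(0, 2**31 - 1))
            if params.task == "MWM":
                trials[mid] = simulate_mwm_trials(float(norm.cdf(ab_z[i])), seed=sub)
            else:
                trials[mid] = simulate_apa_trials(float(norm.cdf(ab_z[i])), seed=sub)
        truth.trajectories = trials  # type: ignore[attr-defined]
    return features, metrics, truth
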