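"""Recovery and calibration experiments on synthetic ground truth.

Each function runs the real analysis path (velocity -> immobility -> ripple
filter -> envelope -> detection -> spectrogram -> features -> scores) on
data from :mod:`ripplescreen.synthetic` and scores it against what was
planted. These are the package's own validation experiments; the session
sizes are chosen so a full run completes in minutes on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from .preprocess import (
    FilterKind,
    FilterSpec,
    bandpass_filter,
    immobility_intervals,
    velocity_from_position,
)
from .session_io import LFPSession, Region
from .spectral import SpectrogramSpec, multitaper_spectrogram, sg_power_during_swrs, zscore_spectrogram
from .swr import DetectionParams, detect_swrs, envelope_stats, ripple_envelope, swr_abundance
from .synthetic import (
    MINIMAL_MONTAGE,
    CohortSimParams,
    LFPSimParams,
    simulate_cohort,
    simulate_lfp_session,
)

__all__ = [
    "run_detection",
    "detection_recovery",
    "abundance_recovery",
    "sg_feature",
    "sg_null_and_monotonicity",
    "prediction_recovery",
    "type1_calibration",
]

#: session sized to yield ~630 s of qualified immobility (three 240 s
#: immobile blocks, each qualifying after 30 s)
DETECTION_FIXTURE = dict(
    duration_s=900.0,
    immobility_schedule=((60.0, 240.0),),
    montage=tuple(MINIMAL_MONTAGE),
)


def run_detection(session: LFPSession, params: DetectionParams = DetectionParams()):
    """Velocity -> immobility -> ripple envelope -> SWR events on a session.

    Returns (events, immobility, stats). Detection runs on the first CA1
    pyramidal-layer site.
    """
    vel = velocity_from_position(session.position)
    immobility = immobility_intervals(vel)
    pyr = session.sites_in_region(Region.CA1_PYR)
    trace = session.signals[session.site_index(pyr[0].site_id)]
    spec = FilterSpec(FilterKind.FIR_EQUIRIPPLE_BANDPASS, *params.band, 10)
    env = ripple_envelope(bandpass_filter(trace, spec, session.sample_rate),
                          session.sample_rate, params.smoothing_sigma_s)
    stats = envelope_stats(env, immobility, session.sample_rate)
    events = detect_swrs(env, stats, params, immobility, session.sample_rate,
                         pyr[0].site_id)
    return events, immobility, stats


def _match_events(planted: np.ndarray, detected: np.ndarray, window_s: float = 0.05):
    """Greedy nearest matching of detected onsets to planted onsets."""
    used = np.zeros(len(detected), dtype=bool)
    errors = []
    for onset in planted:
        if len(detected) == 0:
            continue
        d = np.abs(detected - onset)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= window_s:
            used[j] = True
            errors.append(float(detected[j] - onset))
    return np.asarray(errors), used


def detection_recovery(seed: int, ripple_rate_hz: float = 0.2,
                       ripple_amp_sd: float = 8.0) -> dict:
    """Sensitivity, false-positive rate, and onset error on one session."""
    params = LFPSimParams(seed=seed, ripple_rate_hz=ripple_rate_hz,
                          ripple_amp_sd=ripple_amp_sd, **DETECTION_FIXTURE)
    session, truth = simulate_lfp_session(params)
    events, immobility, _ = run_detection(session)
    onsets = np.array([ev.trigger_s for ev in events])
    errors, used = _match_events(truth.event_times, onsets)
    n_planted = len(truth.event_times)
    sensitivity = len(errors) / n_planted if n_planted else math.nan
    fp_rate = float(np.sum(~used)) / immobility.total_s
    within_10ms = float(np.mean(np.abs(errors) <= 0.010)) if len(errors) else math.nan
    return dict(
        n_planted=n_planted,
        n_detected=len(events),
        sensitivity=sensitivity,
        false_positive_hz=fp_rate,
        onset_frac_within_10ms=within_10ms,
        median_abs_onset_error_ms=float(np.median(np.abs(errors)) * 1000) if len(errors) else math.nan,
        abundance_hz=swr_abundance(events, immobility),
        immobility_s=immobility.total_s,
    )


def abundance_recovery(seed: int, n_seeds: int = 100, rate_hz: float = 0.2) -> dict:
    """Abundance estimate vs the planted Poisson rate over many sessions.

    The tolerance is twice the Poisson standard error of the rate over the
    session's qualified immobility time.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    montage = (MINIMAL_MONTAGE[0],)  # detection site only
    errors = []
    within = []
    within_realized = []
    bounds = []
    for s in sub_seeds:
        params = LFPSimParams(seed=int(s), ripple_rate_hz=rate_hz,
                              duration_s=900.0, immobility_schedule=((60.0, 240.0),),
                              montage=montage, sg_mod_amp=0.0, sharp_wave_amp_uv=0.0)
        session, truth = simulate_lfp_session(params)
        events, immobility, _ = run_detection(session)
        est = swr_abundance(events, immobility)
        bound = 2.0 * math.sqrt(rate_hz / immobility.total_s)
        realized = len(truth.event_times) / immobility.total_s
        errors.append(est - rate_hz)
        within.append(abs(est - rate_hz) <= bound)
        within_realized.append(abs(est - realized) <= bound)
        bounds.append(bound)
    mean_est = float(rate_hz + np.mean(errors))
    ensemble_se = 0.5 * float(np.mean(bounds)) / math.sqrt(n_seeds)
    return dict(
        n_seeds=n_seeds,
        planted_rate_hz=rate_hz,
        mean_estimate_hz=mean_est,
        ensemble_se_hz=ensemble_se,
        mean_abs_error_hz=float(np.mean(np.abs(errors))),
        frac_within_2se=float(np.mean(within)),
        frac_within_2se_of_realized=float(np.mean(within_realized)),
    )


def sg_feature(seed: int, sg_mod_amp: float, ripple_rate_hz: float = 0.2) -> float:
    """Full-path SG-power-during-SWRs feature on a CA3 site of one session."""
    params = LFPSimParams(seed=seed, ripple_rate_hz=ripple_rate_hz,
                          sg_mod_amp=sg_mod_amp, **DETECTION_FIXTURE)
    session, _ = simulate_lfp_session(params)
    events, immobility, _ = run_detection(session)
    ca3 = session.sites_in_region(Region.CA3)[0]
    sig = session.signals[session.site_index(ca3.site_id)]
    spec = SpectrogramSpec(freq_range=(10.0, 100.0))
    t_c, freqs, power = multitaper_spectrogram(sig, session.sample_rate, spec)
    z = zscore_spectrogram(power, immobility.contains(t_c))
    return sg_power_during_swrs(z, t_c, freqs, events)


def sg_null_and_monotonicity(seed: int, n_mono_seeds: int = 10,
                             amplitudes=(1.0, 2.0, 3.0, 4.0)) -> dict:
    """SG-feature calibration: null bias and monotonicity in planted amplitude."""
    null_z = sg_feature(seed, sg_mod_amp=0.0)
    rng = np.random.default_rng(seed + 1)
    seeds = rng.integers(0, 2**31 - 1, size=n_mono_seeds)
    n_monotone = 0
    curves = []
    for s in seeds:
        curve = [sg_feature(int(s), a) for a in amplitudes]
        curves.append(curve)
        if all(b > a for a, b in zip(curve, curve[1:])):
            n_monotone += 1
    default_amp = LFPSimParams().sg_mod_amp
    idx = int(np.argmin(np.abs(np.asarray(amplitudes) - default_amp)))
    return dict(
        null_abs_z=abs(null_z),
        default_amp_z=float(np.mean([c[idx] for c in curves])),
        monotone_fraction=n_monotone / n_mono_seeds,
        mean_curve=[float(v) for v in np.mean(curves, axis=0)],
    )


def _one_pair(seed: int, r2_ab: float, r2_sg: float,
              n_screen: int, n_repl: int) -> tuple[float, float]:
    """Recovered cross-cohort prediction R^2 for one screen/replication pair."""
    f_s, m_s, _ = simulate_cohort(CohortSimParams(
        seed=seed, n_mice=n_screen, cohort_label="SCREEN",
        effect_r2_abundance=r2_ab, effect_r2_sg=r2_sg, abundance_mean_hz=0.12))
    f_r, m_r, _ = simulate_cohort(CohortSimParams(
        seed=seed + 1, n_mice=n_repl, cohort_label="REPLICATION",
        effect_r2_abundance=r2_ab, effect_r2_sg=r2_sg, abundance_mean_hz=0.20))
    out = []
    for feat, metric_set in [("swr_abundance_hz", cs.MWM_LEARNING_METRICS),
                             ("sg_z_ca3", cs.MWM_PRECISION_METRICS)]:
        z_s = pd.DataFrame({c: cs.zscore_metric(m_s[c]) for c in metric_set})
        z_r = pd.DataFrame({c: cs.zscore_metric(m_r[c]) for c in metric_set})
        score_s = cs.composite_score(z_s, metric_set, cs.DEFAULT_SIGN_MAP)
        score_r = cs.composite_score(z_r, metric_set, cs.DEFAULT_SIGN_MAP)
        model = cs.fit_linear_predictor(cs.zscore_metric(f_s[feat]), score_s, feat, "screen")
        _, r2, _, _ = cs.predict_and_evaluate(model, cs.zscore_metric(f_r[feat]), score_r)
        out.append(r2)
    return out[0], out[1]


def prediction_recovery(seed: int, n_pairs: int = 100,
                        r2_learning: float = 0.51, r2_precision: float = 0.77,
                        n_screen_learning: int = 16, n_screen_precision: int = 13,
                        n_repl: int = 11) -> dict:
    """Mean recovered cross-cohort R^2 at the planted effect sizes.

    Learning uses screen n=16 mice, precision screen n=13 (CA3 coverage is
    sparser); replication cohorts have n=11.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 2, size=n_pairs)
    learn, prec = [], []
    for s in seeds:
        r2_l, _ = _one_pair(int(s), r2_learning, r2_precision, n_screen_learning, n_repl)
        _, r2_p = _one_pair(int(s) + 10_000_000, r2_learning, r2_precision,
                            n_screen_precision, max(n_repl - 1, 5))
        learn.append(r2_l)
        prec.append(r2_p)
    return dict(
        planted_r2_learning=r2_learning,
        planted_r2_precision=r2_precision,
        mean_recovered_r2_learning=float(np.mean(learn)),
        mean_recovered_r2_precision=float(np.mean(prec)),
        n_pairs=n_pairs,
    )


def type1_calibration(seed: int, n_cohorts: int = 500, alpha: float = 0.05) -> dict:
    """Significance rate of feature-score correlations at planted R^2 = 0.

    Both relationships (abundance->learning, SG->precision) are tested in
    each null cohort; the pooled rejection rate should sit at the nominal
    alpha.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_cohorts)
    n_sig = 0
    n_tests = 0
    for s in seeds:
        f, m, _ = simulate_cohort(CohortSimParams(
            seed=int(s), n_mice=16, effect_r2_abundance=0.0, effect_r2_sg=0.0))
        for feat, metric_set in [("swr_abundance_hz", cs.MWM_LEARNING_METRICS),
                                 ("sg_z_ca3", cs.MWM_PRECISION_METRICS)]:
            z = pd.DataFrame({c: cs.zscore_metric(m[c]) for c in metric_set})
            score = cs.composite_score(z, metric_set, cs.DEFAULT_SIGN_MAP)
            res = cs.correlate(cs.zscore_metric(f[feat]), score.scores)
            n_tests += 1
            n_sig += int(res.p < alpha)
    return dict(n_tests=n_tests, significant_rate=n_sig / n_tests, alpha=alpha)
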