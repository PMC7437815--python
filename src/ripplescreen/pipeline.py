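"""End-to-end orchestration: sessions -> SWR events -> features -> metrics
-> composite scores -> cross-cohort prediction report.

Every number in the report is reproducible by calling the underlying module
functions directly; the pipeline only sequences them and logs counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from .preprocess import (
    FilterKind,
    FilterSpec,
    IntervalSet,
    bandpass_filter,
    immobility_intervals,
    session_passes_inclusion,
    velocity_from_position,
)
from .session_io import LFPSession, Region
from .spectral import SG_BAND, SG_WINDOW, SpectrogramSpec, multitaper_spectrogram, sg_power_during_swrs, zscore_spectrogram
from .swr import DetectionParams, RippleEvent, detect_swrs, envelope_stats, ripple_envelope, swr_abundance

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

__all__ = [
    "PipelineConfig",
    "SessionResult",
    "process_session",
    "events_to_frame",
    "extract_cohort_features",
    "score_cohort",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis, serializable to YAML."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    spectrogram: SpectrogramSpec = field(default_factory=SpectrogramSpec)
    sg_band: tuple[float, float] = SG_BAND
    sg_window: tuple[float, float] = SG_WINDOW
    immobility_threshold_cm_s: float = 1.0
    immobility_qualify_s: float = 30.0
    inclusion_min_immobile_s: float = 600.0
    velocity_sigma_s: float = 0.25
    zref: str = "session"  # session | preevent
    sign_map: dict = field(default_factory=lambda: dict(cs.DEFAULT_SIGN_MAP))
    learning_metrics: list = field(default_factory=lambda: list(cs.MWM_LEARNING_METRICS))
    precision_metrics: list = field(default_factory=lambda: list(cs.MWM_PRECISION_METRICS))
    seed: int = 0

    def validate(self) -> None:
        for m in [*self.learning_metrics, *self.precision_metrics]:
            if m not in self.sign_map:
                raise ValueError(f"metric {m!r} missing from the sign map")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["detection"] = dataclasses.asdict(self.detection)
        d["spectrogram"] = dataclasses.asdict(self.spectrogram)
        d["sign_map"] = {k: cs.Orientation(v).value for k, v in self.sign_map.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        det = d.pop("detection", {})
        if "band" in det:
            det["band"] = tuple(det["band"])
        spec = d.pop("spectrogram", {})
        if spec.get("freq_range"):
            spec["freq_range"] = tuple(spec["freq_range"])
        sign_map = {k: cs.Orientation(v) for k, v in d.pop("sign_map", {}).items()}
        for key in ("sg_band", "sg_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(detection=DetectionParams(**det), spectrogram=SpectrogramSpec(**spec),
                   sign_map=sign_map, **d)


@dataclass
class SessionResult:
    """Outputs of one session: inclusion, events, abundance, SG per region."""

    mouse_id: str
    session_index: int
    included: bool
    exclusion_reason: str | None
    immobility: IntervalSet | None = None
    events: list[RippleEvent] = field(default_factory=list)
    abundance_hz: float = float("nan")
    sg_by_region: dict = field(default_factory=dict)  # Region -> mean z over that region's sites


def process_session(session: LFPSession, config: PipelineConfig | None = None) -> SessionResult:
    """Run preprocessing, SWR detection, and the SG feature on one session.

    SWRs are detected on the first usable CA1 pyramidal-layer site; the
    z-scored slow-gamma feature is computed per site for CA1-sr, CA3, and DG
    and averaged within each region.
    """
    cfg = config or PipelineConfig()
    vel = velocity_from_position(session.position, cfg.velocity_sigma_s)
    immobility = immobility_intervals(vel, cfg.immobility_threshold_cm_s, cfg.immobility_qualify_s)
    if not session_passes_inclusion(immobility, cfg.inclusion_min_immobile_s):
        log.info("session %s/%d excluded: %.0f s immobile", session.mouse_id,
                 session.session_index, immobility.total_s)
        return SessionResult(session.mouse_id, session.session_index, included=False,
                             exclusion_reason=f"immobile {immobility.total_s:.0f} s < "
                                              f"{cfg.inclusion_min_immobile_s:.0f} s")
    pyr = session.sites_in_region(Region.CA1_PYR)
    if not pyr:
        return SessionResult(session.mouse_id, session.session_index, included=False,
                             exclusion_reason="no CA1 pyramidal-layer site")
    det_site = pyr[0]
    fs = session.sample_rate
    trace = session.signals[session.site_index(det_site.site_id)]
    ripple_spec = FilterSpec(FilterKind.FIR_EQUIRIPPLE_BANDPASS, *cfg.detection.band, 10)
    env = ripple_envelope(bandpass_filter(trace, ripple_spec, fs), fs,
                          cfg.detection.smoothing_sigma_s)
    stats = envelope_stats(env, immobility, fs)
    events = detect_swrs(env, stats, cfg.detection, immobility, fs, det_site.site_id)
    log.info("session %s/%d: %d SWRs in %.0f s immobility", session.mouse_id,
             session.session_index, len(events), immobility.total_s)

    sg_by_region: dict = {}
    if events:
        for region in (Region.CA1_SR, Region.CA3, Region.DG):
            vals = []
            for site in session.sites_in_region(region):
                sig = session.signals[session.site_index(site.site_id)]
                t_c, freqs, power = multitaper_spectrogram(sig, fs, cfg.spectrogram)
                if cfg.zref == "preevent":
                    # z-reference: the -500..-250 ms window before each event
                    baseline = np.zeros(len(t_c), dtype=bool)
                    for ev in events:
                        baseline |= (t_c >= ev.trigger_s - 0.5) & (t_c < ev.trigger_s - 0.25)
                else:
                    baseline = immobility.contains(t_c)
                z = zscore_spectrogram(power, baseline)
                vals.append(sg_power_during_swrs(z, t_c, freqs, events, cfg.sg_band, cfg.sg_window))
            if vals:
                sg_by_region[region] = float(np.mean(vals))
    return SessionResult(
        mouse_id=session.mouse_id,
        session_index=session.session_index,
        included=True,
        exclusion_reason=None,
        immobility=immobility,
        events=events,
        abundance_hz=swr_abundance(events, immobility),
        sg_by_region=sg_by_region,
    )


def events_to_frame(results: list[SessionResult]) -> pd.DataFrame:
    """Flatten detected events into the ``events.csv`` layout."""
    rows = []
    for res in results:
        for ev in res.events:
            rows.append(
                dict(mouse_id=res.mouse_id, session=res.session_index,
                     site_id=ev.detection_site, start_s=ev.start_s, peak_s=ev.peak_s,
                     end_s=ev.end_s, peak_sd=ev.peak_sd)
            )
    return pd.DataFrame(rows, columns=["mouse_id", "session", "site_id",
                                       "start_s", "peak_s", "end_s", "peak_sd"])


def extract_cohort_features(results: list[SessionResult]) -> pd.DataFrame:
    """Per-mouse SWR feature table from per-session results.

    Sessions are averaged with equal weight; mice whose sessions were all
    excluded are dropped (with a logged reason). Missing regions stay NaN.
    """
    rows = []
    dropped = set()
    for res in results:
        if not res.included:
            dropped.add(res.mouse_id)
            continue
        rows.append(
            dict(
                mouse_id=res.mouse_id,
                session_index=res.session_index,
                swr_abundance_hz=res.abundance_hz,
                sg_z_ca1sr=res.sg_by_region.get(Region.CA1_SR, np.nan),
                sg_z_ca3=res.sg_by_region.get(Region.CA3, np.nan),
                sg_z_dg=res.sg_by_region.get(Region.DG, np.nan),
            )
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("no included sessions in cohort")
    for m in dropped - set(frame["mouse_id"]):
        log.warning("mouse %s dropped: all sessions excluded", m)
    return frame.groupby("mouse_id").mean().drop(columns=["session_index"])


def score_cohort(metrics: pd.DataFrame, config: PipelineConfig | None = None,
                 task: str = "MWM") -> pd.DataFrame:
    """Z-score the metric table and build both composite scores."""
    cfg = config or PipelineConfig()
    cfg.validate()
    z = pd.DataFrame({c: cs.zscore_metric(metrics[c]) for c in metrics.columns})
    learning = cs.composite_score(z, cfg.learning_metrics, cfg.sign_map, "LEARNING", task)
    precision = cs.composite_score(z, cfg.precision_metrics, cfg.sign_map, "MEMORY_PRECISION", task)
    return pd.DataFrame({"learning_score": learning.scores, "precision_score": precision.scores})


def run_pipeline(
    screen_features: pd.DataFrame,
    screen_metrics: pd.DataFrame,
    repl_features: pd.DataFrame,
    repl_metrics: pd.DataFrame,
    config: PipelineConfig | None = None,
    task: str = "MWM",
) -> dict:
    """Screen -> replication predictive analysis on feature/metric tables.

    Fits the two screen-cohort linear models (z-scored abundance -> learning
    score; z-scored CA3 SG -> precision score), applies them to the
    replication cohort (predictors re-z-scored within that cohort), and
    reports correlations with Holm-Sidak adjustment, leave-one-out
    robustness, and the cross-cohort prediction R^2. Deterministic given its
    inputs and config.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "task": task, "seed": cfg.seed}

    scores_s = score_cohort(screen_metrics, cfg, task)
    scores_r = score_cohort(repl_metrics, cfg, task)

    correlations = {}
    pvals = []
    keys = []
    for feat, score_col in [("swr_abundance_hz", "learning_score"), ("sg_z_ca3", "precision_score")]:
        for cohort, feats, scores in [("screen", screen_features, scores_s),
                                      ("replication", repl_features, scores_r)]:
            x = cs.zscore_metric(feats[feat])
            y = scores[score_col]
            res = cs.correlate(x, y)
            robust, _ = cs.loo_robustness(x, y)
            res.robust_loo = robust
            key = f"{cohort}:{feat}->{score_col}"
            correlations[key] = res
            keys.append(key)
            pvals.append(res.p)
    for key, adj in zip(keys, cs.holm_sidak(pvals)):
        correlations[key].p_adjusted = float(adj)
    report["correlations"] = {
        k: dict(method=v.method, r=v.r, n=v.n, p=v.p, p_adjusted=v.p_adjusted,
                robust_loo=v.robust_loo)
        for k, v in correlations.items()
    }

    prediction = {}
    for feat, score_col, name in [
        ("swr_abundance_hz", "learning_score", "learning"),
        ("sg_z_ca3", "precision_score", "precision"),
    ]:
        model = cs.fit_linear_predictor(
            cs.zscore_metric(screen_features[feat]), scores_s[score_col],
            predictor_name=feat, cohort_label="screen",
        )
        _, r2, f_stat, p = cs.predict_and_evaluate(
            model, cs.zscore_metric(repl_features[feat]), scores_r[score_col]
        )
        prediction[name] = dict(slope=model.slope, intercept=model.intercept,
                                r2=r2, F=f_stat, p=p)
    report["prediction"] = prediction
    # redundancy audit: composite metrics should capture distinct behavior
    component = [*cfg.learning_metrics, *cfg.precision_metrics]
    report["redundancy_kept_metrics"] = cs.redundancy_filter(screen_metrics[component])
    report["n_mice"] = {"screen": int(len(screen_features)), "replication": int(len(repl_features))}
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=float))
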