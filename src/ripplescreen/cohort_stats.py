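"""Composite performance scores, correlation machinery, multiplicity and
enrichment tests, cross-cohort prediction, and robustness checks.

Per-mouse behavioral metrics are z-scored within a cohort, sign-oriented so
that positive always means better-than-average performance, and averaged
into composite scores (learning performance; memory precision). Simple
linear models fitted in a *screen* cohort are applied to z-scored predictors
of a *replication* cohort; the fraction of variance they capture is the
headline prediction statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "Orientation",
    "SignMap",
    "PerformanceScore",
    "LinearPredictor",
    "CorrelationResult",
    "MWM_LEARNING_METRICS",
    "MWM_PRECISION_METRICS",
    "APA_LEARNING_METRICS",
    "APA_PRECISION_METRICS",
    "DEFAULT_SIGN_MAP",
    "zscore_metric",
    "composite_score",
    "redundancy_filter",
    "correlate",
    "holm_sidak",
    "binomial_enrichment",
    "fit_linear_predictor",
    "predict_and_evaluate",
    "loo_robustness",
]


class Orientation(str, Enum):
    HIGHER_IS_BETTER = "HIGHER_IS_BETTER"
    LOWER_IS_BETTER = "LOWER_IS_BETTER"


SignMap = dict  # metric name -> Orientation

# Composite-score definitions. MWM learning: escape-latency slope over days
# 1-2 and 1-3, day-3 latency, and the overnight latency change across the
# first night -- all lower-is-better. MWM precision: probe quadrant time and
# target crossings (higher-is-better) and distance-to-platform AUC
# (lower-is-better) on the early probes. APA learning (day 2): latency to
# first entrance, path length, opposite-quadrant time -- higher-is-better.
# APA precision: entrances on day 2 and per-bout distance from the zone on
# days 2-3 -- lower-is-better.
MWM_LEARNING_METRICS = [
    "mwm_latency_slope_d1_2",
    "mwm_latency_slope_d1_3",
    "mwm_latency_d3",
    "mwm_overnight_change_d1_2",
]
MWM_PRECISION_METRICS = [
    "mwm_probe1_quadrant_pct",
    "mwm_probe2_quadrant_pct",
    "mwm_probe1_crossings",
    "mwm_probe1_auc",
    "mwm_probe2_auc",
]
APA_LEARNING_METRICS = [
    "apa_latency_first_entrance_d2",
    "apa_path_length_d2",
    "apa_opposite_quadrant_pct_d2",
]
APA_PRECISION_METRICS = [
    "apa_entrances_d2",
    "apa_bout_distance_d2",
    "apa_bout_distance_d3",
]

DEFAULT_SIGN_MAP: SignMap = {
    "mwm_latency_slope_d1_2": Orientation.LOWER_IS_BETTER,
    "mwm_latency_slope_d1_3": Orientation.LOWER_IS_BETTER,
    "mwm_latency_d3": Orientation.LOWER_IS_BETTER,
    "mwm_overnight_change_d1_2": Orientation.LOWER_IS_BETTER,
    "mwm_probe1_quadrant_pct": Orientation.HIGHER_IS_BETTER,
    "mwm_probe2_quadrant_pct": Orientation.HIGHER_IS_BETTER,
    "mwm_probe1_crossings": Orientation.HIGHER_IS_BETTER,
    "mwm_probe1_auc": Orientation.LOWER_IS_BETTER,
    "mwm_probe2_auc": Orientation.LOWER_IS_BETTER,
    "apa_latency_first_entrance_d2": Orientation.HIGHER_IS_BETTER,
    "apa_path_length_d2": Orientation.HIGHER_IS_BETTER,
    "apa_opposite_quadrant_pct_d2": Orientation.HIGHER_IS_BETTER,
    "apa_entrances_d2": Orientation.LOWER_IS_BETTER,
    "apa_bout_distance_d2": Orientation.LOWER_IS_BETTER,
    "apa_bout_distance_d3": Orientation.LOWER_IS_BETTER,
}


@dataclass
class PerformanceScore:
    """Composite z-score per mouse; positive = above-average performance."""

    scores: pd.Series
    component_metrics: list[str]
    kind: str  # LEARNING | MEMORY_PRECISION
    task: str  # MWM | APA


@dataclass(frozen=True)
class LinearPredictor:
    """OLS fit of a performance score on a z-scored SWR feature."""

    predictor_name: str
    slope: float
    intercept: float
    source_cohort: str = ""

    def __call__(self, z: np.ndarray | pd.Series):
        return self.intercept + self.slope * z


@dataclass
class CorrelationResult:
    method: str  # PEARSON | SPEARMAN
    r: float
    n: int
    p: float
    p_adjusted: float | None = None
    robust_loo: bool | None = None


def zscore_metric(values: pd.Series | np.ndarray) -> pd.Series:
    """Z-score with the sample SD (n-1); missing values stay missing."""
    s = pd.Series(values, dtype=float)
    ok = s.dropna()
    if len(ok) < 3:
        raise ValueError(f"need >= 3 non-missing values, got {len(ok)}")
    sd = ok.std(ddof=1)
    if not sd > 0:
        raise ValueError("zero variance: z-score undefined")
    return (s - ok.mean()) / sd


def composite_score(
    z_table: pd.DataFrame,
    metrics: list[str],
    sign_map: SignMap,
    kind: str = "LEARNING",
    task: str = "MWM",
) -> PerformanceScore:
    """Sign-oriented mean of z-scored metrics per mouse.

    Metrics oriented LOWER_IS_BETTER enter with inverted sign, so the
    composite is positive for above-average performance. A mouse with fewer
    than half the metrics present gets the missing sentinel.
    """
    missing = [m for m in metrics if m not in sign_map]
    if missing:
        raise KeyError(f"metrics missing from sign map: {missing}")
    absent = [m for m in metrics if m not in z_table.columns]
    if absent:
        raise KeyError(f"metrics missing from z table: {absent}")
    oriented = pd.DataFrame(index=z_table.index)
    for m in metrics:
        sign = -1.0 if Orientation(sign_map[m]) is Orientation.LOWER_IS_BETTER else 1.0
        oriented[m] = sign * z_table[m]
    counts = oriented.notna().sum(axis=1)
    scores = oriented.mean(axis=1)
    scores[counts < math.ceil(len(metrics) / 2)] = np.nan
    return PerformanceScore(scores=scores, component_metrics=list(metrics), kind=kind, task=task)


def redundancy_filter(metric_table: pd.DataFrame, r2_max: float = 0.5) -> list[str]:
    """Greedy redundancy filter: keep metrics in declared column order,
    dropping any metric whose pairwise R^2 with an already-kept metric is
    >= ``r2_max``."""
    cols = list(metric_table.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 metrics")
    kept: list[str] = []
    for c in cols:
        redundant = False
        for k in kept:
            pair = metric_table[[k, c]].dropna()
            if len(pair) < 3:
                continue
            r = pair[k].corr(pair[c])
            if np.isfinite(r) and r * r >= r2_max:
                redundant = True
                break
        if not redundant:
            kept.append(c)
    return kept


def correlate(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    alpha_normality: float = 0.05,
) -> CorrelationResult:
    """Pearson when both variables pass Shapiro-Wilk normality, else Spearman."""
    pair = pd.DataFrame({"x": pd.Series(x, dtype=float).to_numpy(),
                         "y": pd.Series(y, dtype=float).to_numpy()}).dropna()
    if len(pair) < 4:
        raise ValueError(f"need >= 4 paired values, got {len(pair)}")
    xv, yv = pair["x"].to_numpy(), pair["y"].to_numpy()
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("constant input: correlation undefined")
    normal = (
        sstats.shapiro(xv).pvalue >= alpha_normality
        and sstats.shapiro(yv).pvalue >= alpha_normality
    )
    if normal:
        res = sstats.pearsonr(xv, yv)
        return CorrelationResult(method="PEARSON", r=float(res.statistic), n=len(pair),
                                 p=float(res.pvalue))
    res = sstats.spearmanr(xv, yv)
    return CorrelationResult(method="SPEARMAN", r=float(res.statistic), n=len(pair),
                             p=float(res.pvalue))


def holm_sidak(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjustment, returned in input order.

    Sorting p ascending, the i-th adjusted value is
    max_{j<=i} [1 - (1 - p_(j))^(m-j+1)] (1-based), clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def binomial_enrichment(k_significant: int, n_comparisons: int, alpha: float = 0.05) -> float:
    """One-sided exact upper tail P(X >= k), X ~ Binomial(n, alpha)."""
    if not (0 <= k_significant <= n_comparisons):
        raise ValueError("need 0 <= k <= n")
    return float(sstats.binom.sf(k_significant - 1, n_comparisons, alpha))


def fit_linear_predictor(
    predictor_z: pd.Series | np.ndarray,
    score: PerformanceScore | pd.Series,
    predictor_name: str = "predictor",
    cohort_label: str = "",
) -> LinearPredictor:
    """OLS of the performance score on the z-scored feature."""
    y = score.scores if isinstance(score, PerformanceScore) else pd.Series(score, dtype=float)
    pair = pd.DataFrame({"x": pd.Series(predictor_z, dtype=float).to_numpy()[: len(y)],
                         "y": y.to_numpy()}).dropna()
    if len(pair) < 4:
        raise ValueError("need >= 4 paired values")
    if np.std(pair["x"]) == 0:
        raise ValueError("degenerate (constant) predictor")
    fit = sstats.linregress(pair["x"], pair["y"])
    return LinearPredictor(
        predictor_name=predictor_name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        source_cohort=cohort_label,
    )


def predict_and_evaluate(
    model: LinearPredictor,
    predictor_z: pd.Series | np.ndarray,
    actual: PerformanceScore | pd.Series,
) -> tuple[pd.Series, float, float, float]:
    """Apply a screen-cohort model to a target cohort and evaluate it.

    The predictor must already be z-scored *within the target cohort* (this
    is what makes the transfer robust to cohort-level shifts in the raw
    feature). Returns (predicted, r2, F, p) where r2 is the squared Pearson
    correlation of predicted vs actual and F/p come from the simple
    regression of actual on predicted.
    """
    y = actual.scores if isinstance(actual, PerformanceScore) else pd.Series(actual, dtype=float)
    x = pd.Series(predictor_z, dtype=float)
    predicted = pd.Series(model(x.to_numpy()), index=x.index)
    pair = pd.DataFrame({"pred": predicted.to_numpy()[: len(y)], "act": y.to_numpy()}).dropna()
    if len(pair) < 4:
        raise ValueError("need >= 4 paired values")
    fit = sstats.linregress(pair["pred"], pair["act"])
    r2 = float(fit.rvalue**2)
    df = len(pair) - 2
    f_stat = float(fit.rvalue**2 / (1 - fit.rvalue**2) * df) if abs(fit.rvalue) < 1 else math.inf
    return predicted, r2, f_stat, float(fit.pvalue)


def loo_robustness(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
) -> tuple[bool, list[float]]:
    """Leave-one-out robustness of a correlation.

    Re-runs the method-selecting correlation on every n-1 subset; the
    relationship is robust iff every subset stays significant at ``alpha``
    (no single animal drives the result).
    """
    pair = pd.DataFrame({"x": pd.Series(x, dtype=float).to_numpy(),
                         "y": pd.Series(y, dtype=float).to_numpy()}).dropna()
    n = len(pair)
    if n < 5:
        raise ValueError("need >= 5 points for leave-one-out")
    ps: list[float] = []
    for i in range(n):
        sub = pair.drop(pair.index[i])
        ps.append(correlate(sub["x"], sub["y"], alpha_normality).p)
    return all(p < alpha for p in ps), ps
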