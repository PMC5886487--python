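"""Correlation screening, feature-set selection, z-scoring, and ANOVA.

Each candidate metric is correlated (Pearson) with the index of difficulty
across all trials; |r| >= 0.60 counts as strong, 0.30-0.59 moderate,
0.20-0.29 weak, and metrics below 0.20 are excluded from modeling.  The
surviving metrics induce the four predictor sets compared downstream:

* Set I   — movement time alone (the classical Fitts predictor),
* Set II  — every included metric except MT (multimodal fusion),
* Set III — the kinematic subset of II,
* Set IV  — the physiological subset of II.

z-scoring uses the population (1/n) standard deviation; in cross-validation
the parameters are fit on each training fold and applied to its test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as ss

__all__ = [
    "KINEMATIC_METRICS",
    "PHYSIOLOGICAL_METRICS",
    "ALL_METRICS",
    "pearson_r",
    "classify_correlation",
    "screen_features",
    "select_features",
    "zscore",
    "fit_zscore",
    "one_way_anova",
    "CorrelationScreen",
    "MetricScreenRow",
    "MetricSet",
    "FeatureSets",
    "ZScoreParams",
    "DegenerateScreenError",
]

#: Task- and user-space motion metrics (forearm FA, upper arm UA).
KINEMATIC_METRICS = (
    "AngVel_FA",
    "AngVel_UA",
    "LinAcc_FA",
    "LinAcc_UA",
    "Jerk_FA",
    "Jerk_UA",
    "PathStrDev",
    "PathEff",
)

#: Physiological response metrics (EMG, EEG cognitive states, GSR, HR).
PHYSIOLOGICAL_METRICS = (
    "PostD_rms",
    "PectM_rms",
    "PostD_MAV",
    "PectM_MAV",
    "Engagement",
    "Workload",
    "Distraction",
    "SleepOnset",
    "HeadMvL",
    "SC_vr",
    "HR",
)

#: The 20 candidate metrics: physiological + kinematic + movement time.
ALL_METRICS = PHYSIOLOGICAL_METRICS + KINEMATIC_METRICS + ("MT",)

INCLUSION_THRESHOLD = 0.20


class DegenerateScreenError(ValueError):
    """Raised when screening leaves no usable predictor metrics."""


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = ss.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def classify_correlation(r: float) -> str:
    """Strength category from |r|: strong (>=0.60), moderate (>=0.30),
    weak (>=0.20), else excluded.  Sign-blind by design — a strongly
    negative correlate is as informative as a positive one."""
    a = abs(r)
    if a > 1.0 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if a >= 0.60:
        return "strong"
    if a >= 0.30:
        return "moderate"
    if a >= INCLUSION_THRESHOLD:
        return "weak"
    return "excluded"


@dataclass(frozen=True)
class MetricScreenRow:
    """Screening outcome for one metric."""

    metric: str
    r: float
    p: float
    category: str
    included: bool


@dataclass(frozen=True)
class CorrelationScreen:
    """Per-metric screening results, keyed by metric name."""

    rows: dict  # metric -> MetricScreenRow
    threshold: float = INCLUSION_THRESHOLD

    def included_metrics(self) -> list[str]:
        return [m for m, row in self.rows.items() if row.included]

    def excluded_metrics(self) -> list[str]:
        return [m for m, row in self.rows.items() if not row.included]


def screen_features(
    features,
    response,
    metrics=ALL_METRICS,
    threshold: float = INCLUSION_THRESHOLD,
) -> CorrelationScreen:
    """Correlate every metric column against the response (ID) and flag
    inclusion at |r| >= threshold.

    ``features`` is a DataFrame-like with the metric columns; ``response``
    the per-trial difficulty values.
    """
    rows = {}
    y = np.asarray(response, dtype=float)
    for m in metrics:
        r, p = pearson_r(np.asarray(features[m], dtype=float), y)
        rows[m] = MetricScreenRow(
            metric=m,
            r=r,
            p=p,
            category=classify_correlation(r),
            included=abs(r) >= threshold,
        )
    return CorrelationScreen(rows=rows, threshold=threshold)


def screen_from_correlations(
    r_values: dict, threshold: float = INCLUSION_THRESHOLD
) -> CorrelationScreen:
    """Build a screen directly from known correlation coefficients
    (p-values unavailable are reported as NaN)."""
    rows = {
        m: MetricScreenRow(
            metric=m,
            r=float(r),
            p=float("nan"),
            category=classify_correlation(r),
            included=abs(r) >= threshold,
        )
        for m, r in r_values.items()
    }
    return CorrelationScreen(rows=rows, threshold=threshold)


@dataclass(frozen=True)
class MetricSet:
    """One predictor grouping: set id ("I".."IV") and its metric names."""

    set_id: str
    metrics: tuple


@dataclass(frozen=True)
class FeatureSets:
    """The four predictor sets induced by a correlation screen."""

    set_i: MetricSet
    set_ii: MetricSet
    set_iii: MetricSet
    set_iv: MetricSet
    excluded: tuple

    def __iter__(self):
        return iter((self.set_i, self.set_ii, self.set_iii, self.set_iv))

    def by_id(self, set_id: str) -> MetricSet:
        for s in self:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def select_features(screen: CorrelationScreen) -> FeatureSets:
    """Partition the included metrics into the four modeling sets.

    Set I is always {MT}; Set II is every other included metric; Sets III
    and IV split II by modality (kinematic vs physiological).  Raises
    :class:`DegenerateScreenError` when no non-MT metric survives.
    """
    missing = [m for m in ALL_METRICS if m not in screen.rows]
    if missing:
        raise ValueError(f"screen is missing candidate metrics: {missing}")
    included = [m for m in ALL_METRICS if m != "MT" and screen.rows[m].included]
    if not included:
        raise DegenerateScreenError("no metric passed the correlation threshold")
    kin = tuple(m for m in included if m in KINEMATIC_METRICS)
    phys = tuple(m for m in included if m in PHYSIOLOGICAL_METRICS)
    excluded = tuple(
        m for m in ALL_METRICS if m != "MT" and not screen.rows[m].included
    )
    return FeatureSets(
        set_i=MetricSet("I", ("MT",)),
        set_ii=MetricSet("II", tuple(included)),
        set_iii=MetricSet("III", kin),
        set_iv=MetricSet("IV", phys),
        excluded=excluded,
    )


@dataclass(frozen=True)
class ZScoreParams:
    """Per-column mean and population (1/n) standard deviation."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.std) <= 0):
            raise ValueError("z-score std must be > 0 for every column")


def fit_zscore(values) -> ZScoreParams:
    """Estimate z-score parameters on (training) data, population SD."""
    x = np.atleast_2d(np.asarray(values, dtype=float))
    if x.shape[0] == 1 and np.asarray(values).ndim == 1:
        x = x.T
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    if np.any(std == 0):
        bad = np.nonzero(std == 0)[0].tolist()
        raise ValueError(f"constant column(s) {bad}: z-score undefined")
    return ZScoreParams(mean=mean, std=std)


def zscore(values, params: ZScoreParams | None = None) -> np.ndarray:
    """Standardize ``(x - mu) / sigma``; with ``params=None`` the parameters
    are fit on the input itself (mean 0, SD 1 in-sample)."""
    x = np.asarray(values, dtype=float)
    orig_1d = x.ndim == 1
    if orig_1d:
        x = x[:, None]
    if params is None:
        params = fit_zscore(x)
    z = (x - np.asarray(params.mean)) / np.asarray(params.std)
    return z[:, 0] if orig_1d else z


def one_way_anova(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA across difficulty-level groups: returns
    (F, p) with F = between/within mean-square ratio on (k-1, N-k) df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if g.ndim != 1 or g.shape[0] < 2:
            raise ValueError("every group needs at least 2 observations")
    res = ss.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)
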