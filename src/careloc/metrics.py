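"""Accessibility statistics of nearest-facility travel times.

Given each demand point's minutes to its nearest open facility, this module
computes the reporting statistics of the analysis:

* population-weighted and unweighted mean, median and interquartile range
  of travel time (minutes). "Weighted" means population-frequency-weighted
  statistics of the minutes, with cell populations (density × area) as
  weights — the natural reading that keeps the values on the minute scale;
* the share (and absolute population) with travel time strictly exceeding
  a threshold, 40 minutes by default — the regulatory benchmark for access
  to pediatric emergency care;
* the same stratified by urbanization class (urban / intermediate / rural);
* distribution comparisons: Shapiro-Wilk normality screening and the
  two-sided Mann-Whitney U test with tie-corrected normal approximation;
* before/after change reports (absolute, percent, and percentage-point
  deltas for proportions).

Weighted quantiles use the lower weighted quantile without interpolation:
the smallest value whose cumulative weight reaches q of the total. This is
order-statistic exact and reproducible; interpolating conventions give
slightly different medians on small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demand import URBANIZATION_CLASSES, DemandSet
from .errors import ValidationError

DEFAULT_THRESHOLD_MIN = 40.0


def weighted_quantile(
    values: Sequence[float], weights: Sequence[float], q: float
) -> float:
    """Lower weighted quantile: smallest value v with cumweight(≤v) ≥ q·total."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValidationError("values and weights must be equal-length 1-D")
    if np.any(w < 0):
        raise ValidationError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValidationError("weights must not all be zero")
    if not 0 <= q <= 1:
        raise ValidationError("q must be in [0, 1]")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    # tiny relative slack so exact-hit targets are not missed to rounding
    target = q * total - 1e-12 * total
    idx = int(np.searchsorted(cum, target, side="left"))
    idx = min(idx, len(v) - 1)
    return float(v[order][idx])


@dataclass
class AccessMetrics:
    """Travel-time summary for one stratum (minutes; persons for counts)."""

    weighted_mean: float
    weighted_median: float
    weighted_iqr_low: float
    weighted_iqr_high: float
    unweighted_mean: float
    unweighted_median: float
    unweighted_iqr_low: float
    unweighted_iqr_high: float
    prop_above_threshold: float
    population_above_threshold: float
    threshold_minutes: float = DEFAULT_THRESHOLD_MIN
    stratum: str = "overall"

    def __post_init__(self) -> None:
        if not (self.weighted_iqr_low <= self.weighted_median <= self.weighted_iqr_high):
            raise ValidationError("weighted IQR must bracket the weighted median")
        if not (
            self.unweighted_iqr_low <= self.unweighted_median <= self.unweighted_iqr_high
        ):
            raise ValidationError("unweighted IQR must bracket the unweighted median")
        if not 0 <= self.prop_above_threshold <= 1:
            raise ValidationError("prop_above_threshold must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(
    minutes: Sequence[float],
    demand: DemandSet,
    threshold: float = DEFAULT_THRESHOLD_MIN,
    stratum: str = "overall",
) -> AccessMetrics:
    """Summarize nearest-facility minutes over a demand set.

    weighted_mean = Σ pop_c·t_c / Σ pop_c; medians and IQRs are lower
    weighted quantiles at q = 0.25/0.5/0.75 (uniform weights for the
    unweighted family); the threshold share uses strict inequality
    (t > threshold, "exceeding").
    """
    t = np.asarray(minutes, dtype=float)
    if len(t) != demand.m:
        raise ValidationError(
            f"{len(t)} minutes for {demand.m} demand points"
        )
    pop = demand.population
    total_pop = float(pop.sum())
    if total_pop <= 0:
        raise ValidationError("total population must be positive")
    ones = np.ones_like(t)
    above = t > threshold
    return AccessMetrics(
        weighted_mean=float(np.sum(pop * t) / total_pop),
        weighted_median=weighted_quantile(t, pop, 0.5),
        weighted_iqr_low=weighted_quantile(t, pop, 0.25),
        weighted_iqr_high=weighted_quantile(t, pop, 0.75),
        unweighted_mean=float(t.mean()),
        unweighted_median=weighted_quantile(t, ones, 0.5),
        unweighted_iqr_low=weighted_quantile(t, ones, 0.25),
        unweighted_iqr_high=weighted_quantile(t, ones, 0.75),
        prop_above_threshold=float(pop[above].sum() / total_pop),
        population_above_threshold=float(pop[above].sum()),
        threshold_minutes=float(threshold),
        stratum=stratum,
    )


def stratified_metrics(
    minutes: Sequence[float],
    demand: DemandSet,
    threshold: float = DEFAULT_THRESHOLD_MIN,
) -> dict[str, AccessMetrics]:
    """Per-urbanization-class summaries plus the overall one.

    Returned dict maps "overall" and each class present in the demand set
    to its AccessMetrics. Class-level populations above threshold sum to
    the overall population above threshold (partition conservation).
    """
    t = np.asarray(minutes, dtype=float)
    if len(t) != demand.m:
        raise ValidationError(f"{len(t)} minutes for {demand.m} demand points")
    bad = set(demand.urbanization) - set(URBANIZATION_CLASSES)
    if bad:
        raise ValidationError(f"unknown urbanization classes: {sorted(bad)}")
    out = {"overall": summarize(t, demand, threshold, "overall")}
    for cls in URBANIZATION_CLASSES:
        mask = demand.urbanization == cls
        if not np.any(mask):
            continue
        sub = DemandSet(
            ids=[demand.ids[i] for i in np.flatnonzero(mask)],
            xy=demand.xy[mask],
            region_id=demand.region_id[mask],
            urbanization=demand.urbanization[mask],
            density=demand.density[mask],
            cell_area=demand.cell_area[mask],
            mode=demand.mode,
        )
        out[cls] = summarize(t[mask], sub, threshold, cls)
    return out


def metrics_frame(metrics: dict[str, AccessMetrics] | AccessMetrics) -> pd.DataFrame:
    """Tidy one-row-per-stratum DataFrame (CSV-ready)."""
    if isinstance(metrics, AccessMetrics):
        metrics = {metrics.stratum: metrics}
    return pd.DataFrame([m.to_dict() for m in metrics.values()])


@dataclass
class ComparisonResult:
    """Mann-Whitney U (sample a vs b) plus per-sample Shapiro-Wilk p."""

    statistic: float
    p_value: float
    normality_p_a: float
    normality_p_b: float

    def __post_init__(self) -> None:
        for p in (self.p_value, self.normality_p_a, self.normality_p_b):
            if not 0 <= p <= 1:
                raise ValidationError("p-values must lie in [0, 1]")


def _shapiro_subsampled(x: np.ndarray, cap: int = 5000) -> float:
    if len(x) > cap:
        idx = np.linspace(0, len(x) - 1, cap).round().astype(int)
        x = x[idx]
    return float(stats.shapiro(x).pvalue)


def compare_distributions(
    times_a: Sequence[float], times_b: Sequence[float]
) -> ComparisonResult:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation.

    Inputs are the unweighted per-demand-point minutes of two scenarios.
    The returned U is the statistic of the first sample: the number of
    pairs (a > b) plus half the ties. Shapiro-Wilk runs on each sample,
    deterministically subsampled to ≤ 5000 points when larger.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each sample needs at least 3 observations")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        normality_p_a=_shapiro_subsampled(a),
        normality_p_b=_shapiro_subsampled(b),
    )


_PROPORTION_FIELDS = {"prop_above_threshold"}
_COMPARED_FIELDS = (
    "weighted_mean",
    "weighted_median",
    "weighted_iqr_low",
    "weighted_iqr_high",
    "unweighted_mean",
    "unweighted_median",
    "unweighted_iqr_low",
    "unweighted_iqr_high",
    "prop_above_threshold",
    "population_above_threshold",
)


def relative_change(before: AccessMetrics, after: AccessMetrics) -> pd.DataFrame:
    """Before/after deltas for every metric field.

    Columns: field, before, after, absolute_change, percent_change (relative
    %, NaN when the baseline is zero — undefined, not infinite). Proportions
    get an extra row ``<field>_percentage_points`` with the delta on the
    0–100 scale.
    """
    rows = []
    for f in _COMPARED_FIELDS:
        x0 = float(getattr(before, f))
        x1 = float(getattr(after, f))
        delta = x1 - x0
        pct = (delta / x0 * 100.0) if x0 != 0 else float("nan")
        rows.append(
            {"field": f, "before": x0, "after": x1,
             "absolute_change": delta, "percent_change": pct}
        )
        if f in _PROPORTION_FIELDS:
            rows.append(
                {
                    "field": f + "_percentage_points",
                    "before": x0 * 100.0,
                    "after": x1 * 100.0,
                    "absolute_change": delta * 100.0,
                    "percent_change": pct,
                }
            )
    return pd.DataFrame(rows)
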