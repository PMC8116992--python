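"""Quality-management analytics over collections of QC records.

Implements the dashboard-style operations a sequencing laboratory uses
to monitor accumulated runs: dataset summaries faceted by year, specimen
type and sequencing type; per-metric distributions within a comparison
group; the standing of one sample inside a reference group (percentile,
z-score, threshold flags); and two-group comparison.

Conventions (fixed, so results are reproducible across versions):

* quantiles use linear interpolation between order statistics (numpy's
  default ``"linear"`` method);
* the standard deviation is the sample sd (n−1 denominator), absent for
  n < 2;
* a sample's percentile within a group uses the mid-rank convention,
  ``100 * (#{x < v} + 0.5 * #{x = v}) / n``, which handles ties
  deterministically;
* missing values are excluded per metric, never imputed.

The optional two-group rank-sum p-value uses the two-sided normal
approximation to the Wilcoxon rank-sum statistic with the usual tie
correction and no continuity correction; it requires n ≥ 8 per group
and is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .elements import BY_PATH
from .model import QcModelError, QcRecord
from .store import SearchFilter


@dataclass(frozen=True)
class Threshold:
    """A pass criterion for one metric: value must be >= (ge) or <= (le)."""

    metric: str
    direction: str  # "ge" | "le"
    value: float

    def __post_init__(self):
        if self.direction not in ("ge", "le"):
            raise ValueError(f"threshold direction must be 'ge' or 'le', got {self.direction!r}")

    def passes(self, v: float) -> bool:
        return v >= self.value if self.direction == "ge" else v <= self.value


class ThresholdConfig:
    """Per-metric thresholds, loadable from a YAML/JSON config file.

    File layout: ``thresholds: [{metric, direction, value}, ...]`` (or a
    bare list).  No thresholds ship enabled by default — cut-offs are
    laboratory policy, not package policy.
    """

    def __init__(self, thresholds: Sequence[Threshold] = ()):
        self.by_metric: Dict[str, Threshold] = {}
        for t in thresholds:
            if t.metric not in BY_PATH or not BY_PATH[t.metric].numeric:
                raise QcModelError(f"threshold on unknown or non-numeric metric: {t.metric!r}")
            self.by_metric[t.metric] = t

    @classmethod
    def from_file(cls, path) -> "ThresholdConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict):
            data = data.get("thresholds", [])
        return cls([Threshold(d["metric"], d["direction"], float(d["value"]))
                    for d in data or []])

    def get(self, metric: str) -> Optional[Threshold]:
        return self.by_metric.get(metric)


@dataclass
class DatasetSummary:
    total: int
    by_year: Dict[object, int]
    by_specimen: Dict[str, int]
    by_sequencing_type: Dict[str, int]

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "by_year": {str(k): v for k, v in self.by_year.items()},
            "by_specimen": dict(self.by_specimen),
            "by_sequencing_type": dict(self.by_sequencing_type),
        }


@dataclass
class DistributionSummary:
    metric: str
    group: SearchFilter
    n: int
    n_missing: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    median: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    threshold: Optional[Threshold] = None
    pass_fraction: Optional[float] = None

    def to_dict(self) -> dict:
        d = {"metric": self.metric, "n": self.n, "n_missing": self.n_missing}
        for k in ("mean", "sd", "median", "q1", "q3", "min", "max", "pass_fraction"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.threshold is not None:
            d["threshold"] = {"direction": self.threshold.direction,
                              "value": self.threshold.value}
        return d


@dataclass
class SampleQualityStatus:
    record_id: str
    metric_status: Dict[str, dict]
    overall_flags: List[str]

    def to_dict(self) -> dict:
        return {"record_id": self.record_id,
                "metric_status": self.metric_status,
                "overall_flags": list(self.overall_flags)}


@dataclass
class GroupComparison:
    metric: str
    group_a: SearchFilter
    group_b: SearchFilter
    summary_a: DistributionSummary
    summary_b: DistributionSummary
    median_difference: float
    rank_sum_p: Optional[float] = None

    def to_dict(self) -> dict:
        d = {"metric": self.metric,
             "summary_a": self.summary_a.to_dict(),
             "summary_b": self.summary_b.to_dict(),
             "median_difference": self.median_difference}
        if self.rank_sum_p is not None:
            d["rank_sum_p"] = self.rank_sum_p
        return d


class StatsError(ValueError):
    pass


def _facet(records, getter) -> Dict[object, int]:
    counts: Dict[object, int] = {}
    for r in records:
        v = getter(r)
        key = "unknown" if v is None else v
        counts[key] = counts.get(key, 0) + 1
    return counts


def dataset_summary(records: Sequence[QcRecord]) -> DatasetSummary:
    """Total count plus counts faceted by year, specimen and assay type.

    Records missing a facet value count under the ``"unknown"`` key, so
    every facet conserves the total.
    """
    return DatasetSummary(
        total=len(records),
        by_year=_facet(records, lambda r: (
            r.sample_prep.sampling_date.year
            if r.sample_prep.sampling_date else None)),
        by_specimen=_facet(records, lambda r: (
            r.sample_prep.specimen_type.value
            if r.sample_prep.specimen_type else None)),
        by_sequencing_type=_facet(records, lambda r: (
            r.sample_prep.sequencing_type.value
            if r.sample_prep.sequencing_type else None)),
    )


def _numeric_metric(metric: str):
    el = BY_PATH.get(metric)
    if el is None:
        raise StatsError(f"unknown metric path: {metric!r}")
    if not el.numeric:
        raise StatsError(f"metric {metric!r} is not numeric")
    return el


def _group_values(records, group: SearchFilter, metric: str):
    members = [r for r in records if group.matches(r)]
    values = np.array([float(r.get(metric)) for r in members
                       if r.get(metric) is not None], dtype=float)
    values.sort()  # fixed summation order: statistics are permutation-invariant
    return members, values


def metric_distribution(records: Sequence[QcRecord], group: SearchFilter,
                        metric: str,
                        threshold: Optional[Threshold] = None) -> DistributionSummary:
    """Descriptive statistics for one metric within one comparison group."""
    _numeric_metric(metric)
    members, values = _group_values(records, group, metric)
    n = values.size
    summary = DistributionSummary(metric=metric, group=group, n=n,
                                  n_missing=len(members) - n, threshold=threshold)
    if n >= 1:
        summary.mean = float(np.mean(values))
        summary.median = float(np.median(values))
        summary.q1 = float(np.quantile(values, 0.25))
        summary.q3 = float(np.quantile(values, 0.75))
        summary.min = float(np.min(values))
        summary.max = float(np.max(values))
        if n >= 2:
            summary.sd = float(np.std(values, ddof=1))
        if threshold is not None:
            summary.pass_fraction = float(
                np.mean([threshold.passes(v) for v in values]))
    elif threshold is not None:
        summary.pass_fraction = None
    return summary


def percentile_of(v: float, values: np.ndarray) -> float:
    """Mid-rank percentile of v within values, in [0, 100]."""
    values = np.asarray(values, dtype=float)
    return float(100.0 * (np.sum(values < v) + 0.5 * np.sum(values == v))
                 / values.size)


def sample_status(record: QcRecord, records: Sequence[QcRecord],
                  group: SearchFilter,
                  thresholds: Optional[ThresholdConfig] = None) -> SampleQualityStatus:
    """Where one sample stands inside a reference group.

    For every numeric metric the record carries: its mid-rank percentile
    in the group, its z-score (absent when the group sd is absent or 0),
    and its threshold verdict if a threshold is configured.  Metrics
    failing their threshold are listed in ``overall_flags``.
    """
    thresholds = thresholds or ThresholdConfig()
    members = [r for r in records if group.matches(r)]
    if not members:
        raise StatsError("comparison group is empty; widen the filter")
    status: Dict[str, dict] = {}
    flags: List[str] = []
    for el in (BY_PATH[p] for p in BY_PATH):
        if not el.numeric:
            continue
        v = record.get(el.path)
        if v is None:
            continue
        v = float(v)
        values = np.array([float(r.get(el.path)) for r in members
                           if r.get(el.path) is not None], dtype=float)
        entry: Dict[str, object] = {"value": v}
        if values.size:
            entry["percentile"] = percentile_of(v, values)
            if values.size >= 2:
                sd = float(np.std(values, ddof=1))
                if sd > 0:
                    entry["z_score"] = (v - float(np.mean(values))) / sd
        t = thresholds.get(el.path)
        if t is not None:
            ok = t.passes(v)
            entry["threshold_pass"] = ok
            if not ok:
                flags.append(el.path)
        status[el.path] = entry
    if not status:
        raise StatsError("record carries no numeric metric")
    return SampleQualityStatus(record_id=record.record_id,
                               metric_status=status, overall_flags=flags)


def rank_sum_p_value(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p by normal approximation with tie
    correction (no continuity correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if sigma2 <= 0:  # all values tied
        return 1.0
    z = (u1 - mu) / np.sqrt(sigma2)
    return float(2.0 * norm.sf(abs(z)))


def compare_groups(records: Sequence[QcRecord], metric: str,
                   group_a: SearchFilter, group_b: SearchFilter,
                   threshold: Optional[Threshold] = None,
                   rank_sum: bool = False) -> GroupComparison:
    """Compare one metric's distribution between two sample groups.

    Raises if either group has no record with the metric present.  The
    rank-sum p-value is opt-in and reported only when both groups have
    at least 8 non-missing values.
    """
    _numeric_metric(metric)
    summary_a = metric_distribution(records, group_a, metric, threshold)
    summary_b = metric_distribution(records, group_b, metric, threshold)
    for name, s in (("group_a", summary_a), ("group_b", summary_b)):
        if s.n < 1:
            raise StatsError(f"{name} has no records with non-missing {metric}")
    p = None
    if rank_sum and summary_a.n >= 8 and summary_b.n >= 8:
        _, va = _group_values(records, group_a, metric)
        _, vb = _group_values(records, group_b, metric)
        p = rank_sum_p_value(va, vb)
    return GroupComparison(
        metric=metric, group_a=group_a, group_b=group_b,
        summary_a=summary_a, summary_b=summary_b,
        median_difference=summary_a.median - summary_b.median,
        rank_sum_p=p)
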