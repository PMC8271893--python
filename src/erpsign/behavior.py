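"""Behavioural and latency summary arithmetic.

Reproduces the study's table conventions: per-shape means and
*population* standard deviations (divisor ``n``, the convention the
published summary rows use) of per-subject correct/incorrect counts,
error rates as a ratio of mean counts, per-component latency summaries,
and correct-vs-incorrect gap times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import refdata
from .synth import TrialRecord

__all__ = [
    "ShapeSummary",
    "LatencySummary",
    "mean_and_popsd",
    "summarize_behavior",
    "aggregate_shape_summaries",
    "summarize_latencies",
    "latency_gaps",
]


def mean_and_popsd(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation (divisor n)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_and_popsd requires at least one value")
    return float(arr.mean()), float(arr.std(ddof=0))


@dataclass
class ShapeSummary:
    """Per-group, per-shape behavioural summary across subjects.

    ``error_rate`` is a fraction in [0, 1].  ``error_rate_mean_of_ratios``
    carries the alternative convention (mean of per-subject error rates)
    when it was computed from raw trials.
    """

    group: str
    shape: str
    mean_correct: float
    sd_correct: float
    mean_incorrect: float
    sd_incorrect: float
    error_rate: float
    error_rate_mean_of_ratios: Optional[float] = None
    n_subjects: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mean_correct < 0 or self.mean_incorrect < 0:
            raise ValueError("mean counts must be non-negative")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must lie in [0, 1]")


def ratio_of_means_error_rate(mean_correct: float, mean_incorrect: float) -> float:
    """Error rate as mean incorrect count over mean total count."""
    total = mean_correct + mean_incorrect
    if total <= 0:
        raise ValueError("cannot form an error rate from zero mean counts")
    return mean_incorrect / total


def summarize_behavior(trials: Sequence[TrialRecord]) -> list[ShapeSummary]:
    """Per group x shape: mean/popsd of per-subject correct and incorrect
    counts, plus the error rate (ratio-of-means convention).

    Subjects contributing zero trials to a group x shape cell are simply
    absent from that cell; a subject present in the log but with no
    usable rows anywhere triggers a warning.
    """
    if len(trials) == 0:
        raise ValueError("summarize_behavior requires a non-empty trial log")
    df = pd.DataFrame({
        "subject_id": [t.subject_id for t in trials],
        "group": [t.group for t in trials],
        "shape": [t.shape for t in trials],
        "is_correct": [t.is_correct for t in trials],
    })
    out: list[ShapeSummary] = []
    for (group, shape), cell in df.groupby(["group", "shape"], sort=True):
        counts = cell.groupby("subject_id")["is_correct"].agg(["sum", "count"])
        n_corr = counts["sum"].to_numpy(dtype=float)
        n_inc = (counts["count"] - counts["sum"]).to_numpy(dtype=float)
        if np.any(counts["count"].to_numpy() == 0):  # pragma: no cover
            warnings.warn(f"subject with zero trials in {group}/{shape} excluded")
        mean_c, sd_c = mean_and_popsd(n_corr)
        mean_i, sd_i = mean_and_popsd(n_inc)
        per_subject_rates = n_inc / (n_corr + n_inc)
        out.append(ShapeSummary(
            group=group, shape=shape,
            mean_correct=mean_c, sd_correct=sd_c,
            mean_incorrect=mean_i, sd_incorrect=sd_i,
            error_rate=ratio_of_means_error_rate(mean_c, mean_i),
            error_rate_mean_of_ratios=float(per_subject_rates.mean()),
            n_subjects=len(counts),
        ))
    return out


def aggregate_shape_summaries(summaries: Sequence[ShapeSummary]) -> ShapeSummary:
    """Group-average row: mean over the per-shape means, popsd across the
    shape means, and the ratio-of-means error rate of those averages."""
    if len(summaries) == 0:
        raise ValueError("no summaries to aggregate")
    groups = {s.group for s in summaries}
    if len(groups) != 1:
        raise ValueError(f"summaries mix groups: {sorted(groups)}")
    mean_c, sd_c = mean_and_popsd([s.mean_correct for s in summaries])
    mean_i, sd_i = mean_and_popsd([s.mean_incorrect for s in summaries])
    return ShapeSummary(
        group=groups.pop(), shape="avg",
        mean_correct=mean_c, sd_correct=sd_c,
        mean_incorrect=mean_i, sd_incorrect=sd_i,
        error_rate=ratio_of_means_error_rate(mean_c, mean_i),
    )


@dataclass
class LatencySummary:
    """Per-component latency mean/popsd for one group and answer condition."""

    group: str
    condition: str
    mean_ms: dict[str, float] = field(default_factory=dict)
    sd_ms: dict[str, float] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)


def summarize_latencies(group: str, condition: str,
                        per_trace: Iterable[Mapping[str, Optional[float]]],
                        ) -> LatencySummary:
    """Summarise detected component latencies across traces.

    ``per_trace`` yields one mapping component name -> latency (ms) per
    averaged trace (e.g. per shape, or per subject); ``None`` entries are
    skipped.
    """
    values: dict[str, list[float]] = {c: [] for c in refdata.COMPONENTS}
    for row in per_trace:
        for comp in refdata.COMPONENTS:
            v = row.get(comp)
            if v is not None:
                values[comp].append(float(v))
    summary = LatencySummary(group=group, condition=condition)
    for comp, vals in values.items():
        if vals:
            m, s = mean_and_popsd(vals)
            summary.mean_ms[comp] = m
            summary.sd_ms[comp] = s
            summary.n[comp] = len(vals)
    return summary


def latency_gaps(correct: LatencySummary, incorrect: LatencySummary,
                 ndigits: int | None = 0) -> dict[str, float]:
    """Per-component gap time: mean incorrect latency minus mean correct.

    Positive gaps mean the incorrect answers' component is delayed.
    Components absent from either summary are omitted.  ``ndigits=0``
    (default) rounds to whole milliseconds; ``None`` leaves gaps unrounded.
    """
    if correct.group != incorrect.group:
        raise ValueError(f"group mismatch: {correct.group!r} vs {incorrect.group!r}")
    gaps: dict[str, float] = {}
    for comp in refdata.COMPONENTS:
        if comp in correct.mean_ms and comp in incorrect.mean_ms:
            gap = incorrect.mean_ms[comp] - correct.mean_ms[comp]
            gaps[comp] = gap if ndigits is None else round(gap, ndigits)
    return gaps
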