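"""Time-weighted occupancy analysis and cross-replication aggregation.

Occupancy is analysed as a piecewise-constant function of continuous time,
never sampled at fixed clock points, so the occupancy distribution of a
replication is exact given its event trace. The per-unit summary measures
are:

* ``mean_total_occupancy`` — time-averaged beds occupied;
* ``pct_time_within_allocated`` — % of time occupancy <= allocated beds
  (occupancy exactly equal to the allocated base counts as *within*, since
  flex is defined as beds in addition to it);
* ``mean_flex_required`` — expected beds in use beyond the allocated base,
  sum over k > allocated of (k - allocated) P(occupancy = k);
* ``pct_time_at_full`` — % of time at the allocated + flex ceiling;
* ``occupancy_histogram`` — time-in-state probability per bed count.

Aggregation across replications pools time (for equal-length result
windows this equals the mean of per-replication values); between-replication
variance provides Monte-Carlo standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccupancyTrace",
    "UnitMetrics",
    "AggregateResults",
    "occupancy_histogram",
    "unit_metrics",
    "entry_delay_stats",
    "aggregate",
]


@dataclass(frozen=True)
class OccupancyTrace:
    """Piecewise-constant occupancy record: value ``values[i]`` holds on
    ``[times[i], times[i+1])``, the last value until ``t_end``."""

    times: np.ndarray
    values: np.ndarray
    t_end: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("trace must contain at least one breakpoint")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("occupancy must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def histogram(self, window_start: float, window_end: float, max_level: int | None = None):
        return occupancy_histogram(self, window_start, window_end, max_level)

    def integral(self, window_start: float, window_end: float) -> float:
        """Integral of occupancy over the window (bed-days)."""
        hist = self.histogram(window_start, window_end)
        return float(np.arange(hist.size) @ hist) * (window_end - window_start)


def occupancy_histogram(
    trace: OccupancyTrace,
    window_start: float,
    window_end: float,
    max_level: int | None = None,
) -> np.ndarray:
    """Time-in-state probabilities: entry ``k`` is the fraction of the window
    spent with occupancy exactly ``k``."""
    if not window_end > window_start:
        raise ValueError(f"empty window [{window_start}, {window_end}]")
    if window_start < trace.times[0] or window_end > trace.t_end + 1e-12:
        raise ValueError("window extends beyond trace coverage")
    edges = np.append(trace.times, trace.t_end)
    lo = np.clip(edges[:-1], window_start, window_end)
    hi = np.clip(edges[1:], window_start, window_end)
    durations = hi - lo
    n = int(trace.values.max()) + 1 if max_level is None else max_level + 1
    hist = np.bincount(trace.values, weights=durations, minlength=n)
    if max_level is not None and hist.size > n:
        raise ValueError(f"trace reaches occupancy {hist.size - 1} above max_level {max_level}")
    return hist / (window_end - window_start)


@dataclass(frozen=True)
class UnitMetrics:
    """Per-unit summary of a time-in-state occupancy distribution."""

    allocated: int
    total: int
    mean_total_occupancy: float
    pct_time_within_allocated: float
    mean_flex_required: float
    pct_time_at_full: float
    occupancy_histogram: np.ndarray


def unit_metrics(histogram: np.ndarray, allocated: int, total: int) -> UnitMetrics:
    """Summarise a time-in-state histogram defined on occupancies 0..total."""
    if allocated > total:
        raise ValueError(f"allocated {allocated} exceeds total capacity {total}")
    hist = np.zeros(total + 1)
    h = np.asarray(histogram, dtype=float)
    if h.size > total + 1 and np.any(h[total + 1:] > 0):
        raise ValueError("histogram has mass above total capacity")
    hist[: min(h.size, total + 1)] = h[: total + 1]
    if abs(hist.sum() - 1.0) > 1e-9:
        raise ValueError(f"histogram mass {hist.sum()} != 1")
    k = np.arange(total + 1)
    return UnitMetrics(
        allocated=allocated,
        total=total,
        mean_total_occupancy=float(k @ hist),
        pct_time_within_allocated=100.0 * float(hist[: allocated + 1].sum()),
        mean_flex_required=float((k[allocated + 1:] - allocated) @ hist[allocated + 1:]),
        pct_time_at_full=100.0 * float(hist[total]),
        occupancy_histogram=hist,
    )


@dataclass(frozen=True)
class AggregateResults:
    """Cross-replication, time-pooled summary.

    ``unit_metrics`` maps unit name to :class:`UnitMetrics` computed on the
    pooled histogram; ``unit_se`` holds the Monte-Carlo standard error of
    each scalar measure, estimated from the between-replication variance.
    Entry statistics cover arrivals in the results window: ``pct_delayed``
    is the percentage that found no free bed on arrival and had to wait (or,
    under the loss policy, were turned away); ``mean_delay`` is the mean
    wait among delayed arrivals (None when none were delayed).
    """

    config_name: str
    n_replications: int
    unit_metrics: dict
    unit_se: dict
    pct_delayed: float
    pct_delayed_se: float
    mean_delay: float | None
    pct_arrivals_found_full: float
    total_arrivals: int


_SCALARS = (
    "mean_total_occupancy",
    "pct_time_within_allocated",
    "mean_flex_required",
    "pct_time_at_full",
)


def entry_delay_stats(results: Sequence, warmup: float | None = None):
    """Pooled entry-delay statistics over the results windows.

    Returns ``(pct_delayed, mean_delay)``; ``mean_delay`` is None when no
    arrival was delayed (and both are None with zero arrivals). ``warmup``
    is accepted for interface symmetry; each replication already scopes its
    statistics to its own results window.
    """
    arrivals = sum(r.win_arrivals for r in results)
    if arrivals == 0:
        return None, None
    delayed = sum(r.win_delayed + r.win_lost for r in results)
    waits = np.concatenate(
        [np.asarray(r.win_entry_waits, dtype=float) for r in results]
        or [np.empty(0)]
    )
    positive = waits[waits > 0]
    mean_delay = float(positive.mean()) if positive.size else None
    return 100.0 * delayed / arrivals, mean_delay


def aggregate(results: Sequence, config, settings) -> AggregateResults:
    """Pool replications sharing one configuration into summary measures."""
    if not results:
        raise ValueError("at least one replication is required")
    names = {r.config_name for r in results}
    if len(names) > 1:
        raise ValueError(f"mixed configurations cannot be aggregated: {sorted(names)}")
    windows = {(r.warmup, r.horizon) for r in results}
    if len(windows) > 1:
        raise ValueError("replications have differing result windows")

    w0, h = results[0].warmup, results[0].horizon
    w1 = w0 + h
    R = len(results)

    per_unit_metrics: dict[str, UnitMetrics] = {}
    per_unit_se: dict[str, dict[str, float]] = {}
    for u in config.units:
        total = u.total_beds
        hists = np.array(
            [occupancy_histogram(r.traces[u.name], w0, w1, max_level=total) for r in results]
        )
        pooled = hists.mean(axis=0)
        per_unit_metrics[u.name] = unit_metrics(pooled, u.allocated_beds, total)
        per_rep = [unit_metrics(hrow, u.allocated_beds, total) for hrow in hists]
        per_unit_se[u.name] = {
            k: float(np.std([getattr(m, k) for m in per_rep], ddof=1) / math.sqrt(R))
            if R > 1
            else float("nan")
            for k in _SCALARS
        }

    pct_delayed, mean_delay = entry_delay_stats(results)
    arrivals = sum(r.win_arrivals for r in results)
    found_full = sum(r.win_found_full for r in results)
    per_rep_frac = [
        100.0 * (r.win_delayed + r.win_lost) / r.win_arrivals
        for r in results
        if r.win_arrivals > 0
    ]
    pct_delayed_se = (
        float(np.std(per_rep_frac, ddof=1) / math.sqrt(len(per_rep_frac)))
        if len(per_rep_frac) > 1
        else float("nan")
    )

    return AggregateResults(
        config_name=results[0].config_name,
        n_replications=R,
        unit_metrics=per_unit_metrics,
        unit_se=per_unit_se,
        pct_delayed=0.0 if pct_delayed is None else pct_delayed,
        pct_delayed_se=pct_delayed_se,
        mean_delay=mean_delay,
        pct_arrivals_found_full=100.0 * found_full / arrivals if arrivals else 0.0,
        total_arrivals=arrivals,
    )
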