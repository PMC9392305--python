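"""Canned validation configurations and estimators.

Small single-unit and tandem configurations whose stationary behaviour is
known in closed form (Erlang loss / truncated Poisson, M/M/c with capped
queue, exact tandem-with-blocking CTMC), plus helpers that run the engine
on them and return Monte-Carlo estimates with between-replication standard
errors. Shared by the ``oracle-check`` CLI subcommand, the test suite and
the acceptance script.
"""

from __future__ import annotations

import math

import numpy as np

from .config import (
    ArrivalSpec,
    LOSSpec,
    PathwayConfig,
    RouteSpec,
    SimulationSettings,
    UnitSpec,
    validate_config,
)
from .engine import run_replication
from .metrics import occupancy_histogram

__all__ = [
    "loss_config",
    "tandem_config",
    "simulate_loss_fraction",
    "simulate_occupancy",
    "simulate_tandem",
    "simulate_pasta",
]

_STROKE = "stroke"


def _unit(name, beds, los, routes, flex=0) -> UnitSpec:
    return UnitSpec(
        name=name,
        allocated_beds=beds,
        flex_beds=flex,
        los={_STROKE: los},
        routes={_STROKE: tuple(routes)},
    )


def loss_config(
    rate: float,
    mean: float,
    servers: int,
    family: str = "exponential",
    cv: float | None = None,
    entry_policy: str = "loss",
    name: str | None = None,
) -> PathwayConfig:
    """Single ward, ``servers`` beds, direct discharge home.

    With ``entry_policy="loss"`` this is an M/G/c/c loss system with offered
    load ``rate * mean``; with ``"wait"`` it is the M/G/c queue."""
    config = PathwayConfig(
        name=name or f"loss_c{servers}_{family}",
        units=(
            _unit("ward", servers, LOSSpec(family, mean, cv),
                  [RouteSpec("home", 1.0, 0.0)]),
        ),
        arrivals=ArrivalSpec(
            base_rate=rate, entry_unit="ward", entry_policy=entry_policy
        ),
        sinks=frozenset({"home"}),
    )
    assert validate_config(config) == []
    return config


def tandem_config(
    rate: float,
    mean_a: float,
    mean_b: float,
    cap_a: int,
    cap_b: int,
    entry_policy: str = "loss",
    family: str = "exponential",
) -> PathwayConfig:
    """Two units in series with blocking-after-service, then home."""
    config = PathwayConfig(
        name=f"tandem_{cap_a}_{cap_b}",
        units=(
            _unit("A", cap_a, LOSSpec(family, mean_a), [RouteSpec("B", 1.0, 0.0)]),
            _unit("B", cap_b, LOSSpec(family, mean_b), [RouteSpec("home", 1.0, 0.0)]),
        ),
        arrivals=ArrivalSpec(base_rate=rate, entry_unit="A", entry_policy=entry_policy),
        sinks=frozenset({"home"}),
    )
    assert validate_config(config) == []
    return config


def _pooled_se(per_rep: np.ndarray):
    """Mean and between-replication standard error along axis 0."""
    per_rep = np.asarray(per_rep, dtype=float)
    mean = per_rep.mean(axis=0)
    n = per_rep.shape[0]
    se = per_rep.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.full_like(mean, np.nan)
    return mean, se


def simulate_loss_fraction(config: PathwayConfig, settings: SimulationSettings):
    """Fraction of arrivals turned away (loss policy), with standard error."""
    fracs = []
    for i in range(settings.replications):
        r = run_replication(config, settings, i)
        if r.win_arrivals:
            fracs.append(r.win_lost / r.win_arrivals)
    est, se = _pooled_se(np.asarray(fracs))
    return float(est), float(se)


def simulate_occupancy(config: PathwayConfig, settings: SimulationSettings, unit: str):
    """Pooled time-in-state occupancy distribution of one unit and its
    per-level standard errors."""
    u = config.unit(unit)
    w0, w1 = settings.warmup, settings.warmup + settings.horizon
    hists = []
    for i in range(settings.replications):
        r = run_replication(config, settings, i)
        hists.append(occupancy_histogram(r.traces[unit], w0, w1, max_level=u.total_beds))
    return _pooled_se(np.asarray(hists))


def simulate_loss_summary(config: PathwayConfig, settings: SimulationSettings, unit: str = "ward"):
    """One pass over the replications of a loss configuration, returning
    ``(loss_frac, loss_se, occupancy, occupancy_se)``."""
    u = config.unit(unit)
    w0, w1 = settings.warmup, settings.warmup + settings.horizon
    fracs, hists = [], []
    for i in range(settings.replications):
        r = run_replication(config, settings, i)
        if r.win_arrivals:
            fracs.append(r.win_lost / r.win_arrivals)
        hists.append(occupancy_histogram(r.traces[unit], w0, w1, max_level=u.total_beds))
    frac, frac_se = _pooled_se(np.asarray(fracs))
    occ, occ_se = _pooled_se(np.asarray(hists))
    return float(frac), float(frac_se), occ, occ_se


def simulate_tandem(config: PathwayConfig, settings: SimulationSettings):
    """Pooled occupancy distributions of both tandem units (A then B)."""
    ua, ub = config.units[0], config.units[1]
    w0, w1 = settings.warmup, settings.warmup + settings.horizon
    ha, hb = [], []
    for i in range(settings.replications):
        r = run_replication(config, settings, i)
        ha.append(occupancy_histogram(r.traces[ua.name], w0, w1, max_level=ua.total_beds))
        hb.append(occupancy_histogram(r.traces[ub.name], w0, w1, max_level=ub.total_beds))
    occ_a, se_a = _pooled_se(np.asarray(ha))
    occ_b, se_b = _pooled_se(np.asarray(hb))
    return occ_a, occ_b, se_a, se_b


def simulate_pasta(config: PathwayConfig, settings: SimulationSettings):
    """Arrival-epoch vs time-average full-capacity probabilities.

    Returns ``(arrival_frac, arrival_se, time_frac, time_se)`` for the entry
    unit: the fraction of arrivals that found it at full allocated+flex
    capacity, and the fraction of time it spent there. With Poisson arrivals
    the two agree (PASTA) up to Monte-Carlo error.
    """
    entry = config.arrivals.entry_unit
    total = config.unit(entry).total_beds
    w0, w1 = settings.warmup, settings.warmup + settings.horizon
    arr_frac, time_frac = [], []
    for i in range(settings.replications):
        r = run_replication(config, settings, i)
        if r.win_arrivals:
            arr_frac.append(r.win_found_full / r.win_arrivals)
        hist = occupancy_histogram(r.traces[entry], w0, w1, max_level=total)
        time_frac.append(hist[total])
    a, a_se = _pooled_se(np.asarray(arr_frac))
    t, t_se = _pooled_se(np.asarray(time_frac))
    return float(a), float(a_se), float(t), float(t_se)
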