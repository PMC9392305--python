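import numpy as np
import pytest

from bedflex.config import LOSSpec, SimulationSettings
from bedflex.engine import run_replication
from bedflex.metrics import (
    OccupancyTrace,
    aggregate,
    entry_delay_stats,
    occupancy_histogram,
    unit_metrics,
)

from conftest import short_settings, single_unit_config


def trace(times, values, t_end):
    return OccupancyTrace(np.asarray(times, float), np.asarray(values), t_end)


def test_histogram_constant_occupancy():
    h = occupancy_histogram(trace([0.0], [3], 10.0), 0.0, 10.0)
    assert h[3] == pytest.approx(1.0)
    assert h.sum() == pytest.approx(1.0)


def test_histogram_two_levels():
    h = occupancy_histogram(trace([0.0, 2.0], [1, 2], 4.0), 0.0, 4.0)
    assert h[1] == pytest.approx(0.5)
    assert h[2] == pytest.approx(0.5)


def test_histogram_respects_window():
    h = occupancy_histogram(trace([0.0, 2.0], [1, 2], 4.0), 2.0, 4.0)
    assert h[2] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        occupancy_histogram(trace([0.0], [1], 4.0), 3.0, 3.0)


def test_trace_invariants_enforced():
    with pytest.raises(ValueError):
        OccupancyTrace(np.array([0.0, 0.0]), np.array([1, 2]), 4.0)
    with pytest.raises(ValueError):
        OccupancyTrace(np.array([0.0]), np.array([-1]), 4.0)


@pytest.mark.parametrize(
    "hist, allocated, total, expected",
    [
        # all mass two beds above allocated
        ({7: 1.0}, 5, 10, dict(mean_flex_required=2.0, pct_time_within_allocated=0.0)),
        # empty unit
        ({0: 1.0}, 5, 10, dict(pct_time_within_allocated=100.0, mean_flex_required=0.0,
                               pct_time_at_full=0.0, mean_total_occupancy=0.0)),
        # half at 20, half at 23 with allocated 22
        ({20: 0.5, 23: 0.5}, 22, 32, dict(pct_time_within_allocated=50.0,
                                          mean_flex_required=0.5,
                                          mean_total_occupancy=21.5)),
    ],
)
def test_unit_metrics_arithmetic(hist, allocated, total, expected):
    h = np.zeros(total + 1)
    for k, p in hist.items():
        h[k] = p
    m = unit_metrics(h, allocated, total)
    for key, value in expected.items():
        assert getattr(m, key) == pytest.approx(value), key


def test_unit_metrics_rejects_bad_input():
    with pytest.raises(ValueError):
        unit_metrics(np.array([1.0]), allocated=2, total=1)
    with pytest.raises(ValueError):
        unit_metrics(np.array([0.5, 0.4]), allocated=1, total=1)  # mass != 1


def test_entry_delay_stats_edge_cases():
    config = single_unit_config(allocated=3, los=LOSSpec("fixed", 1.0))
    r = run_replication(config, short_settings(horizon=5.0), arrival_schedule=[0.0, 1.0])
    assert entry_delay_stats([r]) == (0.0, None)
    empty = run_replication(config, short_settings(horizon=5.0), arrival_schedule=[])
    assert entry_delay_stats([empty]) == (None, None)


def test_aggregate_single_and_identical_replications():
    config = single_unit_config(allocated=2, los=LOSSpec("lognormal", 2.0, 0.8), rate=0.8)
    settings = SimulationSettings(replications=1, horizon=60.0, warmup=10.0, base_seed=2)
    r = run_replication(config, settings, 0)
    agg1 = aggregate([r], config, settings)
    m = agg1.unit_metrics["U"]
    w0, w1 = 10.0, 70.0
    direct = occupancy_histogram(r.traces["U"], w0, w1, max_level=2)
    assert np.allclose(m.occupancy_histogram, direct)
    # aggregating the same replication twice equals the single-replication case
    agg2 = aggregate([r, r], config, settings)
    assert np.allclose(
        agg2.unit_metrics["U"].occupancy_histogram, m.occupancy_histogram
    )


def test_pooled_equals_mean_of_per_replication_metrics():
    config = single_unit_config(allocated=2, flex=1, los=LOSSpec("exponential", 2.0), rate=1.0)
    settings = SimulationSettings(replications=8, horizon=50.0, warmup=10.0, base_seed=4)
    results = [run_replication(config, settings, i) for i in range(8)]
    agg = aggregate(results, config, settings)
    per_rep = [
        unit_metrics(occupancy_histogram(r.traces["U"], 10.0, 60.0, max_level=3), 2, 3)
        for r in results
    ]
    for key in ("mean_total_occupancy", "pct_time_within_allocated",
                "mean_flex_required", "pct_time_at_full"):
        pooled = getattr(agg.unit_metrics["U"], key)
        assert pooled == pytest.approx(np.mean([getattr(m, key) for m in per_rep]), abs=1e-9)


def test_aggregate_rejects_mixed_configurations():
    a = single_unit_config(allocated=2, name="a")
    b = single_unit_config(allocated=2, name="b")
    s = SimulationSettings(replications=1, horizon=10.0, warmup=0.0, base_seed=0)
    ra = run_replication(a, s, 0, arrival_schedule=[0.0])
    rb = run_replication(b, s, 0, arrival_schedule=[0.0])
    with pytest.raises(ValueError, match="mixed"):
        aggregate([ra, rb], a, s)


def test_mean_occupancy_consistent_with_trace_integral():
    config = single_unit_config(allocated=3, flex=2, los=LOSSpec("gamma", 2.5, 0.7), rate=1.2)
    s = SimulationSettings(replications=1, horizon=80.0, warmup=20.0, base_seed=9)
    r = run_replication(config, s, 0)
    hist = occupancy_histogram(r.traces["U"], 20.0, 100.0, max_level=5)
    mean_from_hist = float(np.arange(6) @ hist)
    assert mean_from_hist * 80.0 == pytest.approx(r.traces["U"].integral(20.0, 100.0), abs=1e-9)
    assert hist.sum() == pytest.approx(1.0, abs=1e-9)
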