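import numpy as np
import pytest

from bedflex.config import LOSSpec, RouteSpec, SimulationSettings
from bedflex.engine import run_replication
from bedflex.metrics import entry_delay_stats

from conftest import make_unit, short_settings, single_unit_config, tandem_fixture_config
from bedflex.config import ArrivalSpec, PathwayConfig


def test_no_arrivals_means_empty_system():
    config = single_unit_config()
    r = run_replication(config, short_settings(horizon=10.0), arrival_schedule=[], event_log=True)
    assert r.arrivals_total == 0
    assert np.all(r.traces["U"].values == 0)
    assert r.event_log == []
    assert r.win_arrivals == 0


def test_entry_wait_hand_trace():
    """Two arrivals into a 1-bed ward with a fixed 2-day stay: the second
    waits exactly one day and the ward is continuously occupied."""
    config = single_unit_config(allocated=1, flex=0, los=LOSSpec("fixed", 2.0))
    r = run_replication(config, short_settings(horizon=4.0), arrival_schedule=[0.0, 1.0])
    stays = r.patients()
    assert stays["admit"].tolist() == [0.0, 2.0]
    assert stays["depart"].tolist() == [2.0, 4.0]
    assert r.win_delayed == 1
    assert entry_delay_stats([r]) == (50.0, 1.0)
    assert r.traces["U"].integral(0.0, 4.0) == pytest.approx(4.0)
    hist = r.traces["U"].histogram(0.0, 4.0)
    assert hist[1] == pytest.approx(1.0)  # occupancy exactly 1 throughout


def test_tandem_blocking_hand_trace():
    """Blocking after service: the second patient is ready at t=1.5 but holds
    its upstream bed for 2.5 days until the downstream bed frees at t=4."""
    config = tandem_fixture_config()
    r = run_replication(config, short_settings(horizon=7.0), arrival_schedule=[0.0, 0.5])
    stays = r.patients().set_index(["patient_id", "unit"])
    assert stays.loc[(1, "A"), "ready"] == pytest.approx(1.5)
    assert stays.loc[(1, "A"), "depart"] == pytest.approx(4.0)
    blocked = stays.loc[(1, "A"), "depart"] - stays.loc[(1, "A"), "ready"]
    assert blocked == pytest.approx(2.5)
    # A is occupied continuously over [0, 4): integral = 0.5*1 + 0.5*2 + 3*1
    assert r.traces["A"].integral(0.0, 4.0) == pytest.approx(4.5)
    assert r.traces["A"].histogram(0.0, 4.0)[0] == pytest.approx(0.0)


def test_event_log_byte_stable_across_runs():
    config = tandem_fixture_config()
    logs = [
        run_replication(config, short_settings(horizon=7.0),
                        arrival_schedule=[0.0, 0.5], event_log=True).event_log
        for _ in range(2)
    ]
    assert logs[0] == logs[1]
    stochastic = single_unit_config(allocated=2, los=LOSSpec("lognormal", 2.0, 0.9), rate=1.0)
    s = short_settings(horizon=50.0, base_seed=5)
    logs = [run_replication(stochastic, s, 0, event_log=True).event_log for _ in range(2)]
    assert logs[0] == logs[1]


def test_mimic_readiness_uses_mimic_los():
    config = single_unit_config(
        allocated=2, los=LOSSpec("fixed", 5.0), mimic_los=LOSSpec("fixed", 1.0),
        mimic_fraction=1.0,
    )
    r = run_replication(config, short_settings(horizon=3.0),
                        arrival_schedule=[(0.0, "mimic"), (0.5, "stroke")])
    stays = r.patients().set_index("patient_id")
    assert stays.loc[0, "class"] == "mimic"
    assert stays.loc[0, "ready"] == pytest.approx(1.0)
    assert 1 not in stays.index  # stroke still in unit at t_end


def test_departure_frees_bed_for_same_instant_arrival():
    config = single_unit_config(allocated=1, los=LOSSpec("fixed", 2.0))
    r = run_replication(config, short_settings(horizon=5.0), arrival_schedule=[0.0, 2.0])
    assert r.win_delayed == 0
    stays = r.patients()
    assert stays["admit"].tolist() == [0.0, 2.0]


def test_two_step_cascade_in_one_c_phase():
    """A downstream departure admits the blocked patient, whose freed bed in
    turn admits the entry waiter — two conditional events at one instant."""
    config = PathwayConfig(
        name="cascade",
        units=(
            make_unit("A", 1, 0, LOSSpec("fixed", 1.0), [RouteSpec("B", 1.0, 0.0)]),
            make_unit("B", 1, 0, LOSSpec("fixed", 1.0), [RouteSpec("home", 1.0, 0.0)]),
        ),
        arrivals=ArrivalSpec(1.0, "A"),
        sinks=frozenset({"home"}),
    )
    r = run_replication(config, short_settings(horizon=6.0), arrival_schedule=[0.0, 0.5, 0.6])
    stays = r.patients().set_index(["patient_id", "unit"])
    # at t=2: patient 0 leaves B, patient 1 transfers A->B, patient 2 enters A
    assert stays.loc[(0, "B"), "depart"] == pytest.approx(2.0)
    assert stays.loc[(1, "B"), "admit"] == pytest.approx(2.0)
    assert stays.loc[(2, "A"), "admit"] == pytest.approx(2.0)


def test_blocked_transfer_fifo_is_by_readiness_time():
    config = PathwayConfig(
        name="fifo",
        units=(
            make_unit("A", 2, 0, LOSSpec("fixed", 1.0), [RouteSpec("B", 1.0, 0.0)]),
            make_unit("B", 1, 0, LOSSpec("fixed", 5.0), [RouteSpec("home", 1.0, 0.0)]),
        ),
        arrivals=ArrivalSpec(1.0, "A"),
        sinks=frozenset({"home"}),
    )
    # patient 0 fills B at t=1; patients 1 and 2 block in A at 1.2 and 1.4
    r = run_replication(config, short_settings(horizon=20.0),
                        arrival_schedule=[0.0, 0.2, 0.4])
    stays = r.patients().set_index(["patient_id", "unit"])
    assert stays.loc[(1, "B"), "admit"] == pytest.approx(6.0)   # earlier-ready first
    assert stays.loc[(2, "B"), "admit"] == pytest.approx(11.0)


def test_occupancy_ceiling_and_conservation_under_load():
    config = single_unit_config(
        allocated=2, flex=1, los=LOSSpec("lognormal", 3.0, 1.0), rate=1.5
    )
    settings = SimulationSettings(replications=1, horizon=200.0, warmup=20.0, base_seed=13)
    r = run_replication(config, settings, 0)
    assert r.traces["U"].values.max() <= 3
    r.check_conservation()
    assert r.arrivals_total == r.departures_total + r.in_system_end


def test_post_readiness_delay_holds_bed_then_releases():
    config = single_unit_config(allocated=1, los=LOSSpec("fixed", 1.0))
    unit = config.units[0]
    delayed_unit = make_unit("U", 1, 0, LOSSpec("fixed", 1.0),
                             [RouteSpec("home", 1.0, 1.5)])
    config = PathwayConfig("delay", (delayed_unit,), config.arrivals, config.sinks)
    r = run_replication(config, short_settings(horizon=5.0), arrival_schedule=[0.0])
    stays = r.patients()
    assert stays.loc[0, "ready"] == pytest.approx(1.0)
    assert stays.loc[0, "depart"] == pytest.approx(2.5)  # bed held 1.5 further days
    assert r.traces["U"].integral(0.0, 5.0) == pytest.approx(2.5)
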