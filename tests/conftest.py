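from pathlib import Path

import pytest
from hypothesis import settings as hyp_settings

from bedflex.config import (
    ArrivalSpec,
    LOSSpec,
    PathwayConfig,
    RouteSpec,
    SimulationSettings,
    UnitSpec,
)

hyp_settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
hyp_settings.load_profile("ci")

CONFIG_DIR = Path(__file__).resolve().parent.parent / "configs"


@pytest.fixture(scope="session")
def config_dir() -> Path:
    return CONFIG_DIR


@pytest.fixture(scope="session")
def option1_path(config_dir) -> Path:
    return config_dir / "option1.yaml"


def make_unit(name, allocated, flex, los, routes, mimic_los=None, mimic_routes=None):
    los_map = {"stroke": los}
    if mimic_los is not None:
        los_map["mimic"] = mimic_los
    routes_map = {"stroke": tuple(routes)}
    if mimic_routes is not None:
        routes_map["mimic"] = tuple(mimic_routes)
    return UnitSpec(name, allocated, flex, los_map, routes_map)


def single_unit_config(
    allocated=1,
    flex=0,
    los=LOSSpec("fixed", 2.0),
    rate=1.0,
    entry_policy="wait",
    mimic_fraction=0.0,
    mimic_los=None,
    name="single",
):
    return PathwayConfig(
        name=name,
        units=(
            make_unit("U", allocated, flex, los, [RouteSpec("home", 1.0, 0.0)],
                      mimic_los=mimic_los),
        ),
        arrivals=ArrivalSpec(
            base_rate=rate, entry_unit="U",
            entry_policy=entry_policy, mimic_fraction=mimic_fraction,
        ),
        sinks=frozenset({"home"}),
    )


def tandem_fixture_config(cap_a=2, cap_b=1, los_a=1.0, los_b=3.0, flex_b=0):
    """Deterministic two-unit chain used by the blocking hand trace."""
    return PathwayConfig(
        name="tandem_fixture",
        units=(
            make_unit("A", cap_a, 0, LOSSpec("fixed", los_a), [RouteSpec("B", 1.0, 0.0)]),
            make_unit("B", cap_b, flex_b, LOSSpec("fixed", los_b), [RouteSpec("home", 1.0, 0.0)]),
        ),
        arrivals=ArrivalSpec(base_rate=1.0, entry_unit="A"),
        sinks=frozenset({"home"}),
    )


def short_settings(replications=1, horizon=4.0, warmup=0.0, base_seed=0):
    return SimulationSettings(
        replications=replications, horizon=horizon, warmup=warmup, base_seed=base_seed
    )
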