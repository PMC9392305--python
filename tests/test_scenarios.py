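import filecmp
import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from bedflex.cli import main as cli_main
from bedflex.config import ConfigError, SimulationSettings
from bedflex.engine import run_replication
from bedflex.metrics import aggregate
from bedflex.scenarios import (
    ScenarioPack,
    apply_overrides,
    load_grid,
    run_scenario,
    sensitivity_sweep,
    summary_frame,
    summary_report,
)

from conftest import short_settings, single_unit_config

DESK = SimulationSettings(replications=6, horizon=60.0, warmup=15.0, base_seed=3)


@pytest.fixture(scope="module")
def option1_doc(option1_path):
    return yaml.safe_load(option1_path.read_text())


def test_overrides_by_name_and_index(option1_doc):
    doc = apply_overrides(
        option1_doc,
        [
            {"path": ["units", "Rehab 1", "routes", "stroke", "P3", "fixed_delay"], "value": 3.0},
            {"path": ["units", 0, "flex_beds"], "value": 4},
        ],
    )
    rehab1 = next(u for u in doc["units"] if u["name"] == "Rehab 1")
    p3 = next(r for r in rehab1["routes"]["stroke"] if r["destination"] == "P3")
    assert p3["fixed_delay"] == 3.0
    assert doc["units"][0]["flex_beds"] == 4
    assert option1_doc["units"][0]["flex_beds"] == 10  # base untouched


def test_invalid_override_fails_before_simulation(option1_doc):
    pack = ScenarioPack("bad", option1_doc,
                        ((["units", "Rehab 9", "flex_beds"], 0),))
    with pytest.raises(ConfigError, match="Rehab 9"):
        pack.resolve()
    with pytest.raises(ConfigError, match="Rehab 9"):
        sensitivity_sweep(
            ScenarioPack("base", option1_doc),
            [{"name": "x", "overrides": ((["units", "Rehab 9", "flex_beds"], 0),)}],
            DESK,
        )


def test_run_scenario_outputs_and_determinism(option1_path, tmp_path):
    pack = ScenarioPack.from_file(option1_path)
    settings = SimulationSettings(replications=2, horizon=40.0, warmup=10.0, base_seed=5)
    out1, out2 = tmp_path / "run1", tmp_path / "run2"
    agg1 = run_scenario(pack, settings, out_dir=out1, event_log=True)
    agg2 = run_scenario(pack, settings, out_dir=out2, event_log=True)

    names = {p.name for p in out1.iterdir()}
    assert {"summary.csv", "summary.txt", "manifest.json", "events.csv"} <= names
    assert "histogram_Rehab_1.csv" in names
    for name in sorted(names):
        assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name
    assert agg1.unit_metrics["HASU"].mean_total_occupancy == pytest.approx(
        agg2.unit_metrics["HASU"].mean_total_occupancy
    )
    manifest = json.loads((out1 / "manifest.json").read_text())
    assert manifest["settings"]["base_seed"] == 5
    assert len(manifest["config_sha256"]) == 64


def test_no_rehab_flex_variant_caps_rehab_at_allocated(config_dir):
    pack = ScenarioPack.from_file(config_dir / "option1_no_rehab_flex.yaml")
    config, _ = pack.resolve()
    caps = {u.name: (u.allocated_beds, u.total_beds) for u in config.units}
    assert caps["Rehab 1"] == (30, 30)
    assert caps["Rehab 2"] == (12, 12)
    agg = run_scenario(pack, DESK)
    frame = summary_frame(agg, config)
    rehab = frame.set_index("unit").loc["Rehab 1"]
    assert rehab["total_with_flex"] == 30
    report = summary_report(agg, config)
    assert "30 (30)" in report
    assert "-" in report.splitlines()[4]  # rehab row renders mean flex as '-'


def test_summary_report_formatting():
    config = single_unit_config(allocated=22, flex=10, name="fmt")
    r = run_replication(config, short_settings(horizon=10.0), arrival_schedule=[])
    agg = aggregate([r], config, short_settings(horizon=10.0))
    report = summary_report(agg, config)
    assert "22 (32)" in report
    row = report.splitlines()[2]
    assert "0.0" in row and "100.0" in row  # empty ward: within allocated 100%


def test_sweep_single_point_matches_run_scenario(option1_doc):
    base = ScenarioPack("base", option1_doc)
    direct = run_scenario(ScenarioPack("pt", option1_doc), DESK)
    swept = sensitivity_sweep(base, [{"name": "pt", "overrides": ()}], DESK)["pt"]
    for unit in direct.unit_metrics:
        assert np.allclose(
            swept.unit_metrics[unit].occupancy_histogram,
            direct.unit_metrics[unit].occupancy_histogram,
        )


def test_longer_p3_delay_increases_upstream_pressure(option1_doc, config_dir, tmp_path):
    """Sweeping the rehab -> P3 fixed delay upward under common random
    numbers: rehab and upstream units spend no more time within allocated
    capacity than at baseline."""
    grid = load_grid(config_dir / "sensitivity" / "p3_delay.yaml")
    points = [pt for pt in grid if pt["name"] in ("p3_delay_1.5_baseline", "p3_delay_3.0")]
    settings = SimulationSettings(replications=8, horizon=120.0, warmup=30.0, base_seed=11)
    out = sensitivity_sweep(ScenarioPack("base", option1_doc), points, settings,
                            out_dir=tmp_path)
    base = out["p3_delay_1.5_baseline"]
    slow = out["p3_delay_3.0"]
    for unit in ("Rehab 1", "Rehab 2", "ASU"):
        assert (
            slow.unit_metrics[unit].pct_time_within_allocated
            <= base.unit_metrics[unit].pct_time_within_allocated + 1e-9
        )
    assert (tmp_path / "sweep.csv").exists()


def test_cli_validate_and_run(option1_path, config_dir, tmp_path):
    runner = CliRunner()
    ok = runner.invoke(cli_main, ["validate", "--config", str(option1_path)])
    assert ok.exit_code == 0 and "OK" in ok.output

    bad = tmp_path / "bad.yaml"
    doc = yaml.safe_load(option1_path.read_text())
    doc["units"][0]["allocated_beds"] = -2
    bad.write_text(yaml.safe_dump(doc))
    res = runner.invoke(cli_main, ["validate", "--config", str(bad)])
    assert res.exit_code == 1

    out = tmp_path / "out"
    res = runner.invoke(
        cli_main,
        ["run", "--config", str(option1_path), "--replications", "2",
         "--horizon", "30", "--warmup", "5", "--seed", "1", "--out", str(out)],
    )
    assert res.exit_code == 0, res.output
    assert "HASU" in res.output
    assert (out / "summary.csv").exists()


def test_cli_oracle_check_passes():
    runner = CliRunner()
    res = runner.invoke(
        cli_main, ["oracle-check", "--replications", "60", "--horizon", "200", "--seed", "2"]
    )
    assert res.exit_code == 0, res.output
    assert "all oracle checks passed" in res.output
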