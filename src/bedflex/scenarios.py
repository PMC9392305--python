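"""Scenario packs, sensitivity sweeps and report generation.

A :class:`ScenarioPack` is a base configuration document plus a list of
*overrides*, each a path into the raw document and a replacement value.
Paths address list elements either by integer index or by name (a unit's
``name`` or a route's ``destination``), so a sweep over, say, the fixed
delay from the rehabilitation wards to the P3 care-home service reads as

    path: [units, "Rehab 1", routes, stroke, P3, fixed_delay]
    value: 3.0

Replication ``i`` of every scenario draws from substreams keyed by
``(base_seed, i)``; sweeps therefore run under common random numbers, so
differences between grid points are coupled-path differences, not noise.

Report columns mirror the standard bed-planning summary: per unit, the
allocated capacity (total with flex), mean total occupancy, % time within
allocated capacity, mean flex capacity required, and % time at full
allocated-plus-flex capacity, rounded to one decimal place at the report
layer only (CSV outputs keep full precision plus standard errors).
"""

from __future__ import annotations

import copy
import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (
    ConfigError,
    PathwayConfig,
    SimulationSettings,
    config_digest,
    config_to_dict,
    parse_config,
)
from .engine import ReplicationResult, run_replication
from .metrics import AggregateResults, aggregate

__all__ = [
    "ScenarioPack",
    "apply_overrides",
    "load_grid",
    "run_scenario",
    "sensitivity_sweep",
    "summary_report",
    "summary_frame",
]

_MEASURES = (
    ("mean_total_occupancy", "Mean total occupancy, beds"),
    ("pct_time_within_allocated", "Time within allocated capacity, %"),
    ("mean_flex_required", "Mean flex capacity required, beds"),
    ("pct_time_at_full", "Time at full allocated and flex capacity, %"),
)


@dataclass(frozen=True)
class ScenarioPack:
    """A named scenario: base config document plus parameter overrides."""

    name: str
    base: Mapping[str, Any]
    overrides: tuple = ()

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None, overrides=()):
        doc = yaml.safe_load(Path(path).read_text())
        return cls(name=name or doc.get("name", Path(path).stem), base=doc,
                   overrides=tuple(overrides))

    def resolve(self) -> tuple[PathwayConfig, SimulationSettings]:
        doc = apply_overrides(self.base, self.overrides)
        if self.name:
            doc = dict(doc, name=self.name)
        return parse_config(doc)


def _resolve_step(node: Any, key: Any, path_str: str) -> Any:
    if isinstance(node, Mapping):
        if key not in node:
            raise ConfigError(f"override path {path_str}: key {key!r} not found")
        return key
    if isinstance(node, list):
        if isinstance(key, int):
            if not 0 <= key < len(node):
                raise ConfigError(f"override path {path_str}: index {key} out of range")
            return key
        for i, el in enumerate(node):
            if isinstance(el, Mapping) and key in (el.get("name"), el.get("destination")):
                return i
        raise ConfigError(f"override path {path_str}: no element named {key!r}")
    raise ConfigError(f"override path {path_str}: cannot descend into {type(node).__name__}")


def apply_overrides(doc: Mapping[str, Any], overrides: Sequence) -> dict[str, Any]:
    """Return a deep copy of ``doc`` with each ``(path, value)`` override
    applied. Every path must resolve; a bad path raises :class:`ConfigError`
    before any simulation starts."""
    out = copy.deepcopy(dict(doc))
    for ov in overrides:
        if isinstance(ov, Mapping):
            path, value = ov["path"], ov["value"]
        else:
            path, value = ov
        path_str = "/".join(str(p) for p in path)
        node: Any = out
        for step in path[:-1]:
            node = node[_resolve_step(node, step, path_str)]
        last = _resolve_step(node, path[-1], path_str)
        node[last] = value
    return out


def load_grid(path: str | Path) -> list[dict[str, Any]]:
    """Load a sweep grid file: a list of ``{name, overrides}`` entries."""
    doc = yaml.safe_load(Path(path).read_text())
    points = doc["grid"] if isinstance(doc, Mapping) else doc
    out = []
    for i, pt in enumerate(points):
        out.append(
            {"name": str(pt.get("name", f"point{i}")), "overrides": tuple(pt.get("overrides", ()))}
        )
    return out


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------


def run_scenario(
    pack: ScenarioPack,
    settings: SimulationSettings | None = None,
    out_dir: str | Path | None = None,
    event_log: bool = False,
    progress: Callable[[int, int], None] | None = None,
) -> AggregateResults:
    """Run every replication of a scenario and optionally write outputs.

    Replication ``i`` is seeded deterministically from ``(base_seed, i)``.
    When ``out_dir`` is given, writes ``summary.csv`` (full precision plus
    SE columns), ``summary.txt`` (the rounded report table), one
    ``histogram_<unit>.csv`` per unit, a JSON run manifest, and (optionally)
    ``events.csv``.
    """
    config, cfg_settings = pack.resolve()
    settings = settings or cfg_settings
    results: list[ReplicationResult] = []
    for i in range(settings.replications):
        results.append(run_replication(config, settings, i, event_log=event_log))
        if progress is not None:
            progress(i + 1, settings.replications)
    agg = aggregate(results, config, settings)
    if out_dir is not None:
        _write_outputs(Path(out_dir), pack, config, settings, agg, results, event_log)
    return agg


def sensitivity_sweep(
    base: ScenarioPack,
    grid: Sequence[Mapping[str, Any]],
    settings: SimulationSettings | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, AggregateResults]:
    """Run one scenario per grid point under common random numbers.

    Each grid point is the base pack with extra overrides appended; all
    points share the same seeds, so metric differences across the grid are
    coupled-path effects. Returns results keyed by point name; with
    ``out_dir``, also writes a long-format ``sweep.csv``.
    """
    for pt in grid:  # validate everything before simulating
        ScenarioPack(
            name=pt["name"], base=base.base,
            overrides=base.overrides + tuple(pt.get("overrides", ())),
        ).resolve()
    out: dict[str, AggregateResults] = {}
    rows = []
    for pt in grid:
        pack = ScenarioPack(
            name=pt["name"], base=base.base,
            overrides=base.overrides + tuple(pt.get("overrides", ())),
        )
        agg = run_scenario(pack, settings)
        out[pt["name"]] = agg
        config, _ = pack.resolve()
        for u in config.units:
            m = agg.unit_metrics[u.name]
            row = {"scenario": pt["name"], "unit": u.name,
                   "allocated": u.allocated_beds, "total_with_flex": u.total_beds}
            row.update({k: getattr(m, k) for k, _ in _MEASURES})
            rows.append(row)
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out_path / "sweep.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def summary_frame(results: AggregateResults, config: PathwayConfig) -> pd.DataFrame:
    """Full-precision per-unit summary with Monte-Carlo standard errors."""
    rows = []
    for u in config.units:
        m = results.unit_metrics[u.name]
        se = results.unit_se[u.name]
        row = {
            "option": config.name,
            "unit": u.name,
            "allocated": u.allocated_beds,
            "total_with_flex": u.total_beds,
        }
        for key, _ in _MEASURES:
            row[key] = getattr(m, key)
            row[key + "_se"] = se[key]
        rows.append(row)
    return pd.DataFrame(rows)


def summary_report(results: AggregateResults, config: PathwayConfig) -> str:
    """Human-readable summary table, one row per unit, 1 d.p. as in standard
    bed-planning reports; a unit with no flex beds renders mean flex as '-'."""
    headers = ["Unit", "Allocated capacity, beds (total with flex)"] + [h for _, h in _MEASURES]
    rows = [headers]
    for u in config.units:
        m = results.unit_metrics[u.name]
        cells = [u.name, f"{u.allocated_beds} ({u.total_beds})"]
        for key, _ in _MEASURES:
            if key == "mean_flex_required" and u.flex_beds == 0:
                cells.append("-")
            else:
                cells.append(f"{getattr(m, key):.1f}")
        rows.append(cells)
    widths = [max(len(r[i]) for r in rows) for i in range(len(headers))]
    lines = ["  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows]
    lines.insert(1, "-" * len(lines[0]))
    delayed = (
        f"Arrivals delayed at entry: {results.pct_delayed:.1f}%"
        + (f" (mean delay {results.mean_delay:.2f} days)" if results.mean_delay else "")
    )
    return "\n".join(lines + ["", delayed, ""])


def _write_outputs(out_path, pack, config, settings, agg, results, event_log):
    out_path.mkdir(parents=True, exist_ok=True)
    summary_frame(agg, config).to_csv(out_path / "summary.csv", index=False)
    (out_path / "summary.txt").write_text(summary_report(agg, config))
    for u in config.units:
        m = agg.unit_metrics[u.name]
        df = pd.DataFrame(
            {
                "occupancy_level": np.arange(m.occupancy_histogram.size),
                "probability": m.occupancy_histogram,
            }
        )
        safe = u.name.replace(" ", "_").replace("/", "_")
        df.to_csv(out_path / f"histogram_{safe}.csv", index=False)
    if event_log:
        with open(out_path / "events.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["replication", "time", "event_kind", "patient_id", "unit", "occupancy_after"]
            )
            for r in results:
                writer.writerows(r.event_log or [])
    manifest = {
        "scenario": pack.name,
        "software": {"name": "bedflex", "version": __version__},
        "config_sha256": config_digest(config, settings),
        "config": config_to_dict(config, settings),
        "overrides": [
            {"path": list(ov["path"]) if isinstance(ov, Mapping) else list(ov[0]),
             "value": ov["value"] if isinstance(ov, Mapping) else ov[1]}
            for ov in pack.overrides
        ],
        "settings": dataclasses.asdict(settings),
        "replication_seeding": "substreams keyed by (base_seed, replication_index, purpose)",
    }
    (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
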