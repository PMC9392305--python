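"""Declarative configuration of a bed pathway.

A pathway is a directed acyclic graph of inpatient *units* (wards), each with
a two-tier capacity: ``allocated_beds`` routinely staffed for the pathway,
plus ``flex_beds`` available at short notice on top of the allocated base.
Patients arrive at a single entry unit as a homogeneous Poisson process,
stay for a sampled length of stay (LOS), and are then routed probabilistically
either to a downstream unit or to an unbounded community *sink* (e.g. the
discharge-to-assess destinations P0/P1/P1+/P3, or home), possibly after a
fixed post-readiness delay served while still occupying the bed.

Lengths of stay are specified by ``(family, mean, cv)`` rather than native
distribution parameters so that configurations stay readable and sensitivity
sweeps only touch interpretable numbers; lognormal and gamma are solved from
moments. Two patient classes exist, ``stroke`` and ``mimic`` (a presentation
initially treated as stroke but with another diagnosis); class-specific LOS
and routing are optional overrides that default to the stroke values.

Time is continuous and measured in days throughout.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "ConfigError",
    "LOSSpec",
    "RouteSpec",
    "UnitSpec",
    "ArrivalSpec",
    "PathwayConfig",
    "SimulationSettings",
    "STROKE",
    "MIMIC",
    "PATIENT_CLASSES",
    "load_config",
    "parse_config",
    "validate_config",
    "apply_growth",
    "config_to_dict",
]

STROKE = "stroke"
MIMIC = "mimic"
PATIENT_CLASSES = (STROKE, MIMIC)

LOS_FAMILIES = ("exponential", "lognormal", "gamma", "fixed")
ENTRY_POLICIES = ("wait", "loss")

#: Protocol defaults applied when a config omits simulation settings.
DEFAULT_REPLICATIONS = 1500
DEFAULT_HORIZON = 365.0
DEFAULT_WARMUP = 100.0


class ConfigError(ValueError):
    """Raised for unparseable or invalid pathway configurations."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LOSSpec:
    """Length-of-stay distribution given by family, mean and coefficient of
    variation.

    ``cv`` is ignored for ``exponential`` (where it is identically 1) and for
    ``fixed`` (identically 0); for ``lognormal`` and ``gamma`` the native
    parameters are solved from the two moments.
    """

    family: str
    mean: float
    cv: float = None  # type: ignore[assignment]  # normalised in __post_init__

    def __post_init__(self) -> None:
        cv = self.cv
        if self.family == "exponential":
            cv = 1.0
        elif self.family == "fixed":
            cv = 0.0
        elif cv is None:
            cv = 1.0
        object.__setattr__(self, "cv", float(cv))
        object.__setattr__(self, "mean", float(self.mean))

    def native_params(self) -> dict[str, float]:
        """Moment-matched native parameters of the distribution."""
        m, cv = self.mean, self.cv
        if self.family == "exponential":
            return {"scale": m}
        if self.family == "fixed":
            return {"value": m}
        if self.family == "lognormal":
            sigma2 = math.log1p(cv * cv)
            return {"mu": math.log(m) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}
        if self.family == "gamma":
            return {"shape": 1.0 / (cv * cv), "scale": m * cv * cv}
        raise ConfigError(f"unsupported LOS family {self.family!r}")

    @classmethod
    def from_native(cls, family: str, **params: float) -> "LOSSpec":
        """Inverse of :meth:`native_params`; used by the round-trip tests."""
        if family == "exponential":
            return cls("exponential", params["scale"])
        if family == "fixed":
            return cls("fixed", params["value"])
        if family == "lognormal":
            mu, sigma = params["mu"], params["sigma"]
            mean = math.exp(mu + sigma * sigma / 2.0)
            cv = math.sqrt(math.expm1(sigma * sigma))
            return cls("lognormal", mean, cv)
        if family == "gamma":
            k, theta = params["shape"], params["scale"]
            return cls("gamma", k * theta, 1.0 / math.sqrt(k))
        raise ConfigError(f"unsupported LOS family {family!r}")


@dataclass(frozen=True)
class RouteSpec:
    """One directed transfer rule leaving a unit.

    ``destination`` is either a downstream unit name or a community sink name;
    ``fixed_delay`` (days) is served in the *source* bed after discharge
    readiness, before any destination capacity check.
    """

    destination: str
    probability: float
    fixed_delay: float = 0.0


@dataclass(frozen=True)
class UnitSpec:
    """One ward: two-tier capacity, per-class LOS and per-class routing.

    ``los`` and ``routes`` map patient class to a spec; the ``mimic`` entry is
    optional and defaults to the ``stroke`` one. ``allocated_beds +
    flex_beds`` is the hard occupancy ceiling.
    """

    name: str
    allocated_beds: int
    flex_beds: int
    los: Mapping[str, LOSSpec]
    routes: Mapping[str, tuple[RouteSpec, ...]]

    @property
    def total_beds(self) -> int:
        return self.allocated_beds + self.flex_beds

    def los_for(self, klass: str) -> LOSSpec:
        return self.los.get(klass, self.los[STROKE])

    def routes_for(self, klass: str) -> tuple[RouteSpec, ...]:
        return self.routes.get(klass, self.routes[STROKE])


@dataclass(frozen=True)
class ArrivalSpec:
    """Poisson arrival process at the entry unit.

    The effective rate is ``base_rate * growth_factor`` (arrivals/day); each
    arrival is independently a mimic with probability ``mimic_fraction``.
    ``entry_policy`` is ``"wait"`` (arrivals finding the entry unit full join
    an unbounded FIFO queue) or ``"loss"`` (they are turned away), the latter
    existing for loss-system validation runs.
    """

    base_rate: float
    entry_unit: str
    growth_factor: float = 1.0
    mimic_fraction: float = 0.0
    entry_policy: str = "wait"


@dataclass(frozen=True)
class PathwayConfig:
    name: str
    units: tuple[UnitSpec, ...]
    arrivals: ArrivalSpec
    sinks: frozenset[str]

    def unit(self, name: str) -> UnitSpec:
        for u in self.units:
            if u.name == name:
                return u
        raise KeyError(name)

    @property
    def unit_names(self) -> tuple[str, ...]:
        return tuple(u.name for u in self.units)


@dataclass(frozen=True)
class SimulationSettings:
    """Replication protocol: results cover (warmup, warmup + horizon] only."""

    replications: int = DEFAULT_REPLICATIONS
    horizon: float = DEFAULT_HORIZON
    warmup: float = DEFAULT_WARMUP
    base_seed: int = 0


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _require(doc: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in doc:
        raise ConfigError(f"{where}: missing required field {key!r}")
    return doc[key]


def _parse_los(doc: Any, where: str) -> LOSSpec:
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{where}: LOS spec must be a mapping")
    family = _require(doc, "family", where)
    if family not in LOS_FAMILIES:
        raise ConfigError(
            f"{where}: unknown LOS family {family!r} (expected one of {LOS_FAMILIES})"
        )
    mean = _require(doc, "mean", where)
    try:
        return LOSSpec(family, float(mean), doc.get("cv"))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: bad LOS parameters ({exc})") from exc


def _parse_routes(doc: Any, where: str) -> tuple[RouteSpec, ...]:
    if not isinstance(doc, Iterable) or isinstance(doc, (str, Mapping)):
        raise ConfigError(f"{where}: routes must be a list")
    routes = []
    for i, r in enumerate(doc):
        w = f"{where}[{i}]"
        if not isinstance(r, Mapping):
            raise ConfigError(f"{w}: route must be a mapping")
        routes.append(
            RouteSpec(
                destination=str(_require(r, "destination", w)),
                probability=float(_require(r, "probability", w)),
                fixed_delay=float(r.get("fixed_delay", 0.0)),
            )
        )
    return tuple(routes)


def _parse_per_class(doc: Any, where: str, parser, what: str) -> dict[str, Any]:
    """Accept either a bare spec (applied to strokes) or a class-keyed map."""
    if isinstance(doc, Mapping) and set(doc) <= set(PATIENT_CLASSES) and doc:
        out = {k: parser(v, f"{where}.{k}") for k, v in doc.items()}
        if STROKE not in out:
            raise ConfigError(f"{where}: {what} must include the 'stroke' class")
        return out
    return {STROKE: parser(doc, where)}


def parse_config(doc: Mapping[str, Any]) -> tuple[PathwayConfig, SimulationSettings]:
    """Build a :class:`PathwayConfig` and :class:`SimulationSettings` from a
    raw mapping (as loaded from YAML/JSON); validates and raises
    :class:`ConfigError` on any violation.
    """
    if not isinstance(doc, Mapping):
        raise ConfigError("config document must be a mapping")
    name = str(doc.get("name", "pathway"))

    arr = _require(doc, "arrivals", "config")
    arrivals = ArrivalSpec(
        base_rate=float(_require(arr, "base_rate", "arrivals")),
        entry_unit=str(_require(arr, "entry_unit", "arrivals")),
        growth_factor=float(arr.get("growth_factor", 1.0)),
        mimic_fraction=float(arr.get("mimic_fraction", 0.0)),
        entry_policy=str(arr.get("entry_policy", "wait")),
    )

    sinks = frozenset(str(s) for s in doc.get("sinks", ()))

    units = []
    for i, u in enumerate(_require(doc, "units", "config")):
        where = f"units[{i}]"
        uname = str(_require(u, "name", where))
        where = f"unit {uname!r}"
        units.append(
            UnitSpec(
                name=uname,
                allocated_beds=int(_require(u, "allocated_beds", where)),
                flex_beds=int(u.get("flex_beds", 0)),
                los=_parse_per_class(_require(u, "los", where), f"{where}.los", _parse_los, "los"),
                routes=_parse_per_class(
                    _require(u, "routes", where), f"{where}.routes", _parse_routes, "routes"
                ),
            )
        )

    config = PathwayConfig(name=name, units=tuple(units), arrivals=arrivals, sinks=sinks)

    sdoc = doc.get("settings", {}) or {}
    settings = SimulationSettings(
        replications=int(sdoc.get("replications", DEFAULT_REPLICATIONS)),
        horizon=float(sdoc.get("horizon", DEFAULT_HORIZON)),
        warmup=float(sdoc.get("warmup", DEFAULT_WARMUP)),
        base_seed=int(sdoc.get("base_seed", 0)),
    )

    violations = validate_config(config) + _validate_settings(settings)
    if violations:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(violations))
    return config, settings


def load_config(path: str | Path) -> tuple[PathwayConfig, SimulationSettings]:
    """Load and validate a pathway configuration file (YAML; JSON accepted).

    Defaults (1500 replications, 365-day horizon, 100-day warm-up) are applied
    where the ``settings`` block omits them.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{loc}: {exc}") from exc
    return parse_config(doc)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_PROB_TOL = 1e-9


def _validate_settings(settings: SimulationSettings) -> list[str]:
    out = []
    if settings.replications < 1:
        out.append(f"settings: replications must be >= 1, got {settings.replications}")
    if not settings.horizon > 0:
        out.append(f"settings: horizon must be > 0, got {settings.horizon}")
    if settings.warmup < 0:
        out.append(f"settings: warmup must be >= 0, got {settings.warmup}")
    return out


def validate_config(config: PathwayConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid).

    Total: never raises on any structurally well-formed :class:`PathwayConfig`.
    """
    out: list[str] = []
    unit_names = [u.name for u in config.units]
    known = set(unit_names) | set(config.sinks)

    if not config.units:
        out.append("config: at least one unit is required")
    if len(set(unit_names)) != len(unit_names):
        out.append("config: duplicate unit names")
    for s in config.sinks & set(unit_names):
        out.append(f"sink {s!r}: name collides with a unit")

    arr = config.arrivals
    if not arr.base_rate > 0:
        out.append(f"arrivals: base_rate must be > 0, got {arr.base_rate}")
    if arr.growth_factor < 0:
        out.append(f"arrivals: growth_factor must be >= 0, got {arr.growth_factor}")
    if not arr.base_rate * arr.growth_factor > 0:
        out.append("arrivals: effective rate (base_rate * growth_factor) must be > 0")
    if not 0.0 <= arr.mimic_fraction <= 1.0:
        out.append(f"arrivals: mimic_fraction must be in [0, 1], got {arr.mimic_fraction}")
    if arr.entry_policy not in ENTRY_POLICIES:
        out.append(f"arrivals: entry_policy must be one of {ENTRY_POLICIES}, got {arr.entry_policy!r}")
    if arr.entry_unit not in unit_names:
        out.append(f"arrivals: entry_unit {arr.entry_unit!r} is not a defined unit")

    for u in config.units:
        if u.allocated_beds < 0:
            out.append(f"unit {u.name!r}: allocated_beds must be >= 0, got {u.allocated_beds}")
        if u.flex_beds < 0:
            out.append(f"unit {u.name!r}: flex_beds must be >= 0, got {u.flex_beds}")
        if u.total_beds < 1:
            out.append(f"unit {u.name!r}: allocated_beds + flex_beds must be >= 1")
        for klass, los in u.los.items():
            w = f"unit {u.name!r} los[{klass}]"
            if los.family not in LOS_FAMILIES:
                out.append(f"{w}: unknown family {los.family!r}")
            if not los.mean > 0:
                out.append(f"{w}: mean must be > 0, got {los.mean}")
            if los.cv < 0:
                out.append(f"{w}: cv must be >= 0, got {los.cv}")
            if los.family == "gamma" and los.cv == 0:
                out.append(f"{w}: gamma requires cv > 0 (use family 'fixed' for cv = 0)")
        for klass, routes in u.routes.items():
            w = f"unit {u.name!r} routes[{klass}]"
            if not routes:
                out.append(f"{w}: a unit must route somewhere (add a sink route)")
                continue
            total = 0.0
            for r in routes:
                total += r.probability
                if not 0.0 <= r.probability <= 1.0:
                    out.append(f"{w} -> {r.destination!r}: probability {r.probability} not in [0, 1]")
                if r.fixed_delay < 0:
                    out.append(f"{w} -> {r.destination!r}: fixed_delay must be >= 0, got {r.fixed_delay}")
                if r.destination not in known:
                    out.append(f"{w} -> {r.destination!r}: destination is neither a unit nor a sink")
            if abs(total - 1.0) > _PROB_TOL:
                out.append(f"{w}: probabilities sum to {total:.6g}, expected 1")

    out.extend(_check_acyclic(config, set(unit_names)))
    return out


def _check_acyclic(config: PathwayConfig, unit_names: set[str]) -> list[str]:
    adj: dict[str, set[str]] = {
        u.name: {
            r.destination
            for routes in u.routes.values()
            for r in routes
            if r.destination in unit_names
        }
        for u in config.units
    }
    WHITE, GREY, BLACK = 0, 1, 2
    colour = dict.fromkeys(adj, WHITE)

    def dfs(node: str, stack: list[str]) -> list[str] | None:
        colour[node] = GREY
        stack.append(node)
        for nxt in adj[node]:
            if colour[nxt] == GREY:
                return stack[stack.index(nxt):] + [nxt]
            if colour[nxt] == WHITE:
                cyc = dfs(nxt, stack)
                if cyc:
                    return cyc
        colour[node] = BLACK
        stack.pop()
        return None

    for node in adj:
        if colour[node] == WHITE:
            cyc = dfs(node, [])
            if cyc:
                return [f"config: route graph contains a cycle: {' -> '.join(cyc)}"]
    return []


# ---------------------------------------------------------------------------
# Derived quantities and serialisation
# ---------------------------------------------------------------------------


def apply_growth(arrivals: ArrivalSpec) -> float:
    """Effective arrival rate (arrivals/day): ``base_rate * growth_factor``."""
    rate = arrivals.base_rate * arrivals.growth_factor
    if not rate > 0:
        raise ConfigError(f"effective arrival rate must be > 0, got {rate}")
    return rate


def _los_to_dict(los: LOSSpec) -> dict[str, Any]:
    d: dict[str, Any] = {"family": los.family, "mean": los.mean}
    if los.family not in ("exponential", "fixed"):
        d["cv"] = los.cv
    return d


def config_to_dict(
    config: PathwayConfig, settings: SimulationSettings | None = None
) -> dict[str, Any]:
    """Serialise back to the plain-mapping form accepted by :func:`parse_config`.

    Round-trips: ``parse_config(config_to_dict(*load_config(p)))`` equals
    ``load_config(p)``.
    """
    doc: dict[str, Any] = {
        "name": config.name,
        "arrivals": {
            "base_rate": config.arrivals.base_rate,
            "growth_factor": config.arrivals.growth_factor,
            "mimic_fraction": config.arrivals.mimic_fraction,
            "entry_unit": config.arrivals.entry_unit,
            "entry_policy": config.arrivals.entry_policy,
        },
        "sinks": sorted(config.sinks),
        "units": [
            {
                "name": u.name,
                "allocated_beds": u.allocated_beds,
                "flex_beds": u.flex_beds,
                "los": {k: _los_to_dict(v) for k, v in u.los.items()},
                "routes": {
                    k: [
                        {
                            "destination": r.destination,
                            "probability": r.probability,
                            "fixed_delay": r.fixed_delay,
                        }
                        for r in routes
                    ]
                    for k, routes in u.routes.items()
                },
            }
            for u in config.units
        ],
    }
    if settings is not None:
        doc["settings"] = {
            "replications": settings.replications,
            "horizon": settings.horizon,
            "warmup": settings.warmup,
            "base_seed": settings.base_seed,
        }
    return doc


def config_digest(config: PathwayConfig, settings: SimulationSettings) -> str:
    """Stable SHA-256 digest of the canonical serialised form."""
    import hashlib

    canon = json.dumps(config_to_dict(config, settings), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
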