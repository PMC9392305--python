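"""Three-phase discrete-event simulation of patient flow.

The engine advances a continuous clock (days) through a schedule of
*unconditional* events and, after each batch, fires *conditional* events
until none remain:

* **A-phase** — advance the clock to the next unconditional event time.
* **B-phase** — execute every unconditional event at that time: patient
  arrivals, discharge readiness (end of LOS), and fixed post-readiness
  delays elapsing.
* **C-phase** — repeatedly attempt conditional events (admissions from the
  entry queue, transfers of blocked patients) until no further event fires;
  a freed bed can cascade upstream, admitting a blocked patient whose own
  bed then admits the next waiter, and so on.

Capacity semantics: a unit's hard ceiling is ``allocated_beds + flex_beds``;
flex beds are assumed instantly available. A patient occupies exactly one
bed from admission until departure from the unit — including while serving
a fixed post-readiness delay and while *blocked* (ready to move but waiting
for downstream space). Arrivals finding the entry unit at full capacity
either join an unbounded FIFO queue (``entry_policy="wait"``, the default)
or are turned away (``"loss"``, used by the loss-system validation runs).

Determinism: simultaneous events execute readiness, then delay-elapsed,
then arrivals; within a kind, lower patient id first. The discharge route
is drawn once, at readiness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from heapq import heappush, heappop
from typing import Sequence

import numpy as np
import pandas as pd

from .config import MIMIC, STROKE, PathwayConfig, SimulationSettings
from .metrics import OccupancyTrace
from .streams import ReplicationStreams

__all__ = ["ReplicationResult", "run_replication", "run_replications"]

# same-time execution order (B-phase)
_READINESS, _DELAY, _ARRIVAL = 0, 1, 2

# patient statuses
_WAITING, _IN_UNIT, _IN_DELAY, _BLOCKED, _DEPARTED, _LOST = range(6)


@dataclass
class ReplicationResult:
    """Everything one replication produces.

    Statistics fields prefixed ``win_`` cover the results window
    ``(warmup, warmup + horizon]`` only; the conservation counters cover the
    whole run from t = 0.
    """

    config_name: str
    replication_index: int
    warmup: float
    horizon: float
    traces: dict[str, OccupancyTrace]

    # conservation (whole run)
    arrivals_total: int = 0
    departures_total: int = 0
    lost_total: int = 0
    in_system_end: int = 0

    # entry statistics (results window)
    win_arrivals: int = 0
    win_delayed: int = 0
    win_found_full: int = 0
    win_lost: int = 0
    win_entry_waits: list = field(default_factory=list)

    # per-unit window statistics for Little's-law checks
    win_unit_admissions: dict = field(default_factory=dict)
    win_unit_departures: dict = field(default_factory=dict)
    win_unit_bedtime: dict = field(default_factory=dict)

    # per-patient stay records: (patient_id, class, unit, admit, ready, depart)
    records: list = field(default_factory=list)
    event_log: list | None = None

    @property
    def t_end(self) -> float:
        return self.warmup + self.horizon

    def patients(self) -> pd.DataFrame:
        """Per-stay record table (one row per completed unit stay)."""
        return pd.DataFrame(
            self.records,
            columns=["patient_id", "class", "unit", "admit", "ready", "depart"],
        )

    def check_conservation(self) -> None:
        lhs = self.arrivals_total
        rhs = self.departures_total + self.lost_total + self.in_system_end
        if lhs != rhs:
            raise AssertionError(
                f"conservation violated: {lhs} arrivals != {self.departures_total} departed "
                f"+ {self.lost_total} lost + {self.in_system_end} in system"
            )


def run_replication(
    config: PathwayConfig,
    settings: SimulationSettings,
    replication_index: int = 0,
    arrival_schedule: Sequence[tuple[float, str]] | Sequence[float] | None = None,
    event_log: bool = False,
) -> ReplicationResult:
    """Simulate one replication of ``warmup + horizon`` days.

    ``arrival_schedule`` optionally injects a deterministic arrival stream
    (a sequence of times, or of ``(time, class)`` pairs) in place of the
    Poisson process — used by the hand-trace regression fixtures and the
    degenerate-load checks. Replication ``i`` draws from substreams keyed by
    ``(settings.base_seed, i)``, so any subset of replications is
    reproducible independently.
    """
    sim = _Simulation(config, settings, replication_index, arrival_schedule, event_log)
    return sim.run()


def run_replications(
    config: PathwayConfig,
    settings: SimulationSettings,
    event_log: bool = False,
) -> list[ReplicationResult]:
    """Run ``settings.replications`` independent replications."""
    return [
        run_replication(config, settings, i, event_log=event_log)
        for i in range(settings.replications)
    ]


class _Simulation:
    def __init__(self, config, settings, replication_index, arrival_schedule, want_log):
        self.config = config
        self.settings = settings
        self.rep = replication_index
        self.t_end = settings.warmup + settings.horizon
        self.warmup = settings.warmup

        units = config.units
        self.n_units = len(units)
        self.unit_names = [u.name for u in units]
        self.unit_index = {u.name: i for i, u in enumerate(units)}
        self.cap = [u.total_beds for u in units]
        self.entry = self.unit_index[config.arrivals.entry_unit]

        # routing tables: per unit, per class -> (cum_probs, destinations, delays)
        # destination is a unit index, or -1 with the sink name alongside
        self.route_tables: list[dict[str, tuple[list, list, list]]] = []
        for u in units:
            per_class = {}
            for klass in u.routes:
                cum, dests, delays = [], [], []
                acc = 0.0
                for r in u.routes[klass]:
                    acc += r.probability
                    cum.append(acc)
                    dests.append(self.unit_index.get(r.destination, -1))
                    delays.append(r.fixed_delay)
                per_class[klass] = (cum, [r.destination for r in u.routes[klass]], dests, delays)
            self.route_tables.append(per_class)

        self.streams = ReplicationStreams(settings.base_seed, replication_index)
        self.los_draws = {}
        for i, u in enumerate(units):
            for klass in set(u.los) | set(u.routes) | {STROKE}:
                self.los_draws[(i, klass)] = self.streams.los(u.name, klass, u.los_for(klass))
        self.route_u = [self.streams.uniforms(f"route:{u.name}") for u in units]
        self.class_u = self.streams.uniforms("class")
        self.arrival_rng = self.streams.generator("arrivals")

        self.mimic_fraction = config.arrivals.mimic_fraction
        self.wait_policy = config.arrivals.entry_policy == "wait"
        self.rate = config.arrivals.base_rate * config.arrivals.growth_factor

        self.schedule_mode = arrival_schedule is not None
        self.injected = list(arrival_schedule) if arrival_schedule is not None else []

        # state
        self.occ = [0] * self.n_units
        self.trace_t = [[0.0] for _ in units]
        self.trace_n = [[0] for _ in units]
        self.transfer_q: list[list[int]] = [[] for _ in units]
        self.entry_q: list[tuple[int, float]] = []
        self.heap: list[tuple[float, int, int]] = []

        # patient state, indexed by id
        self.p_arr: list[float] = []
        self.p_class: list[str] = []
        self.p_status: list[int] = []
        self.p_unit: list[int] = []
        self.p_admit: list[float] = []
        self.p_ready: list[float] = []
        self.p_dest: list[int] = []     # pending destination unit index (-1 = sink)
        self.p_dest_name: list[str] = []

        self.res = ReplicationResult(
            config_name=config.name,
            replication_index=replication_index,
            warmup=settings.warmup,
            horizon=settings.horizon,
            traces={},
            win_unit_admissions={n: 0 for n in self.unit_names},
            win_unit_departures={n: 0 for n in self.unit_names},
            win_unit_bedtime={n: 0.0 for n in self.unit_names},
            event_log=[] if want_log else None,
        )

    def _in_window(self, t: float) -> bool:
        # results window (warmup, warmup + horizon]; with no warm-up the
        # window is closed on the left so a t = 0 arrival is counted
        return (self.warmup < t <= self.t_end) or (self.warmup == 0.0 and t == 0.0)

    # -- patient bookkeeping ------------------------------------------------

    def _new_patient(self, t: float, klass: str | None) -> int:
        pid = len(self.p_arr)
        if klass is None:
            klass = MIMIC if self.class_u.get(pid) < self.mimic_fraction else STROKE
        self.p_arr.append(t)
        self.p_class.append(klass)
        self.p_status.append(_WAITING)
        self.p_unit.append(-1)
        self.p_admit.append(np.nan)
        self.p_ready.append(np.nan)
        self.p_dest.append(-1)
        self.p_dest_name.append("")
        return pid

    def _log(self, t: float, kind: str, pid: int, uidx: int) -> None:
        if self.res.event_log is not None:
            unit = self.unit_names[uidx] if uidx >= 0 else ""
            occ = self.occ[uidx] if uidx >= 0 else ""
            self.res.event_log.append((self.rep, t, kind, pid, unit, occ))

    def _set_occ(self, uidx: int, t: float, delta: int) -> None:
        occ = self.occ[uidx] + delta
        assert 0 <= occ <= self.cap[uidx], (
            f"occupancy {occ} out of [0, {self.cap[uidx]}] at unit {self.unit_names[uidx]}"
        )
        self.occ[uidx] = occ
        tt, nn = self.trace_t[uidx], self.trace_n[uidx]
        if tt[-1] == t:
            nn[-1] = occ
        else:
            tt.append(t)
            nn.append(occ)

    # -- event generation ---------------------------------------------------

    def _push_first_arrival(self) -> None:
        if self.schedule_mode:
            for item in self.injected:
                t, klass = item if isinstance(item, (tuple, list)) else (item, None)
                pid = self._new_patient(float(t), klass)
                heappush(self.heap, (float(t), _ARRIVAL, pid))
        elif self.rate > 0:
            t = float(self.arrival_rng.exponential(1.0 / self.rate))
            pid = self._new_patient(t, None)
            heappush(self.heap, (t, _ARRIVAL, pid))

    def _push_next_arrival(self, t_now: float) -> None:
        if self.schedule_mode or self.rate <= 0:
            return
        t = t_now + float(self.arrival_rng.exponential(1.0 / self.rate))
        if t <= self.t_end:
            pid = self._new_patient(t, None)
            heappush(self.heap, (t, _ARRIVAL, pid))

    # -- B-phase handlers ---------------------------------------------------

    def _handle_arrival(self, pid: int, t: float) -> None:
        self.res.arrivals_total += 1
        in_window = self._in_window(t)
        if in_window:
            self.res.win_arrivals += 1
        e = self.entry
        full = self.occ[e] >= self.cap[e]
        if in_window and full:
            self.res.win_found_full += 1
        self._log(t, "arrival", pid, e)
        self._push_next_arrival(t)
        if not full and not (self.wait_policy and self.entry_q):
            self._admit(e, pid, t)
            if in_window:
                self.res.win_entry_waits.append(0.0)
        elif self.wait_policy:
            self.entry_q.append((pid, t))
            if in_window:
                self.res.win_delayed += 1
        else:
            self.p_status[pid] = _LOST
            self.res.lost_total += 1
            if in_window:
                self.res.win_lost += 1

    def _handle_readiness(self, pid: int, t: float) -> None:
        uidx = self.p_unit[pid]
        self.p_ready[pid] = t
        self._log(t, "readiness", pid, uidx)
        cum, names, dests, delays = self._routes_for(uidx, self.p_class[pid])
        u = self.route_u[uidx].get(pid)
        k = 0
        while k < len(cum) - 1 and u >= cum[k]:
            k += 1
        self.p_dest[pid] = dests[k]
        self.p_dest_name[pid] = names[k]
        delay = delays[k]
        if delay > 0:
            self.p_status[pid] = _IN_DELAY
            heappush(self.heap, (t + delay, _DELAY, pid))
        else:
            self._finish_ready(pid, t)

    def _routes_for(self, uidx: int, klass: str):
        per_class = self.route_tables[uidx]
        return per_class.get(klass) or per_class[STROKE]

    def _finish_ready(self, pid: int, t: float) -> None:
        dest = self.p_dest[pid]
        if dest < 0:  # community sink: bed released unconditionally
            self._release(self.p_unit[pid], pid, t, departed=True)
        else:
            self.p_status[pid] = _BLOCKED
            self.transfer_q[dest].append(pid)

    def _handle_delay_elapsed(self, pid: int, t: float) -> None:
        self._log(t, "delay_elapsed", pid, self.p_unit[pid])
        self._finish_ready(pid, t)

    # -- bed operations -----------------------------------------------------

    def _admit(self, uidx: int, pid: int, t: float) -> None:
        self._set_occ(uidx, t, +1)
        self.p_unit[pid] = uidx
        self.p_admit[pid] = t
        self.p_status[pid] = _IN_UNIT
        if self._in_window(t):
            self.res.win_unit_admissions[self.unit_names[uidx]] += 1
        los = self.los_draws[(uidx, self.p_class[pid])].get(pid)
        heappush(self.heap, (t + los, _READINESS, pid))
        self._log(t, "admission", pid, uidx)

    def _release(self, uidx: int, pid: int, t: float, departed: bool) -> None:
        self._set_occ(uidx, t, -1)
        name = self.unit_names[uidx]
        self.res.records.append(
            (pid, self.p_class[pid], name, self.p_admit[pid], self.p_ready[pid], t)
        )
        if self._in_window(t):
            self.res.win_unit_departures[name] += 1
            self.res.win_unit_bedtime[name] += t - self.p_admit[pid]
        if departed:
            self.p_status[pid] = _DEPARTED
            self.p_unit[pid] = -1
            self.res.departures_total += 1
            self._log(t, "departure", pid, uidx)

    # -- C-phase ------------------------------------------------------------

    def _c_phase(self, t: float) -> None:
        changed = True
        while changed:
            changed = False
            for u in range(self.n_units):
                while self.occ[u] < self.cap[u]:
                    if self.transfer_q[u]:
                        pid = self.transfer_q[u].pop(0)
                        src = self.p_unit[pid]
                        self._release(src, pid, t, departed=False)
                        self._admit(u, pid, t)
                        changed = True
                    elif u == self.entry and self.entry_q:
                        pid, arr_t = self.entry_q.pop(0)
                        if self._in_window(arr_t):
                            self.res.win_entry_waits.append(t - arr_t)
                        self._admit(u, pid, t)
                        changed = True
                    else:
                        break

    # -- main loop ----------------------------------------------------------

    def run(self) -> ReplicationResult:
        self._push_first_arrival()
        heap = self.heap
        handlers = {
            _ARRIVAL: self._handle_arrival,
            _READINESS: self._handle_readiness,
            _DELAY: self._handle_delay_elapsed,
        }
        while heap:
            t = heap[0][0]  # A-phase
            if t > self.t_end:
                break
            while heap and heap[0][0] == t:  # B-phase
                _, kind, pid = heappop(heap)
                handlers[kind](pid, t)
            self._c_phase(t)  # C-phase

        res = self.res
        for i, name in enumerate(self.unit_names):
            res.traces[name] = OccupancyTrace(
                times=np.asarray(self.trace_t[i]),
                values=np.asarray(self.trace_n[i], dtype=np.int64),
                t_end=self.t_end,
            )
        res.in_system_end = sum(
            1 for s in self.p_status if s in (_WAITING, _IN_UNIT, _IN_DELAY, _BLOCKED)
        )
        res.check_conservation()
        return res
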