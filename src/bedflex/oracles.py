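"""Closed-form and exact-numeric references for validating the engine.

The stochastic engine must reproduce, within Monte-Carlo error:

* the Erlang-B blocking probability and truncated-Poisson occupancy of an
  M/G/c/c loss system (insensitivity: only the mean LOS matters), matching
  a single-unit configuration run under the ``loss`` entry policy;
* the exact stationary distribution of a small continuous-time Markov chain
  for a two-unit tandem with blocking-after-service (a patient ready to
  leave unit A holds their bed until unit B has space), obtained by a
  linear solve on the generator matrix;
* the M/M/c queue with capped waiting room, for single-unit configurations
  under the default ``wait`` policy.

Also provided is the deterministic averages-based bed calculation
(arrival rate x mean LOS / target occupancy) that the flex-capacity
analysis complements; comparing it with the loss-model requirement shows
the systematic under-estimation of stochastic peak demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossSystemSpec",
    "erlang_b",
    "erlang_b_required_servers",
    "truncated_poisson_occupancy",
    "mmck_occupancy",
    "TandemStationary",
    "tandem_blocking_exact",
    "averages_based_beds",
]


@dataclass(frozen=True)
class LossSystemSpec:
    """An M/G/c/c loss system: Poisson arrivals, any LOS with the given mean."""

    arrival_rate: float
    mean_los: float
    servers: int

    @property
    def offered_load(self) -> float:
        a = self.arrival_rate * self.mean_los
        if not a > 0:
            raise ValueError(f"offered load must be > 0, got {a}")
        return a


def erlang_b(spec: LossSystemSpec) -> float:
    """Blocking probability via the stable recurrence
    B(0) = 1, B(c) = a B(c-1) / (c + a B(c-1)).

    By insensitivity this holds for any LOS distribution with the given
    mean, which lets the oracle check non-exponential engine configurations.
    """
    if spec.servers < 1:
        raise ValueError("servers must be >= 1")
    a = spec.offered_load
    b = 1.0
    for c in range(1, spec.servers + 1):
        b = a * b / (c + a * b)
    return b


def erlang_b_required_servers(arrival_rate: float, mean_los: float, max_blocking: float) -> int:
    """Smallest c with Erlang-B blocking <= ``max_blocking``."""
    if not 0 < max_blocking < 1:
        raise ValueError("max_blocking must be in (0, 1)")
    c = 1
    while erlang_b(LossSystemSpec(arrival_rate, mean_los, c)) > max_blocking:
        c += 1
    return c


def truncated_poisson_occupancy(spec: LossSystemSpec) -> np.ndarray:
    """Stationary occupancy of the loss system: P(k) proportional to a^k / k!
    for k = 0..c (the Poisson distribution truncated at the server count)."""
    if spec.servers < 1:
        raise ValueError("servers must be >= 1")
    a = spec.offered_load
    k = np.arange(spec.servers + 1)
    logp = k * math.log(a) - np.cumsum(np.concatenate([[0.0], np.log(k[1:])]))
    p = np.exp(logp - logp.max())
    return p / p.sum()


def mmck_occupancy(arrival_rate: float, mean_los: float, servers: int, queue_cap: int) -> np.ndarray:
    """Stationary number-in-system distribution of an M/M/c queue with at
    most ``queue_cap`` waiting (state space 0..c+K, birth-death chain).

    Used to validate single-unit configurations under the ``wait`` entry
    policy: with the cap chosen so the truncated mass is negligible at the
    tested load, this is an exact reference for the unbounded queue.
    """
    if servers < 1 or queue_cap < 0:
        raise ValueError("servers must be >= 1 and queue_cap >= 0")
    mu = 1.0 / mean_los
    n_states = servers + queue_cap + 1
    logp = np.zeros(n_states)
    for n in range(1, n_states):
        service = min(n, servers) * mu
        logp[n] = logp[n - 1] + math.log(arrival_rate / service)
    p = np.exp(logp - logp.max())
    return p / p.sum()


@dataclass(frozen=True)
class TandemStationary:
    """Exact stationary analysis of the two-unit tandem with blocking."""

    states: list  # (queue, serving_A, blocked_A, occupancy_B)
    probabilities: np.ndarray
    occupancy_a: np.ndarray  # marginal of beds occupied in A (serving + blocked)
    occupancy_b: np.ndarray
    p_blocked: float  # P(at least one patient blocked in A)
    p_a_full: float  # P(A at full capacity) = loss/queueing fraction by PASTA
    mean_queue: float


def tandem_blocking_exact(
    arrival_rate: float,
    mean_los_a: float,
    mean_los_b: float,
    cap_a: int,
    cap_b: int,
    queue_cap: int = 0,
    max_states: int = 20000,
) -> TandemStationary:
    """Solve the CTMC of a tandem A -> B -> out with exponential LOS and
    blocking-after-service, exactly (global balance, linear solve).

    State ``(q, s, b, nB)``: q patients queued at entry (0 with the loss
    policy), s in service in A, b ready-but-blocked in A (each holding an A
    bed), nB occupying B. Blocked patients exist only while B is full, and
    a B departure instantly pulls the longest-blocked patient across (and a
    freed A bed pulls from the queue).
    """
    if cap_a < 1 or cap_b < 1:
        raise ValueError("capacities must be >= 1")
    lam, mu_a, mu_b = arrival_rate, 1.0 / mean_los_a, 1.0 / mean_los_b

    states = []
    for q in range(queue_cap + 1):
        for s in range(cap_a + 1):
            for b in range(cap_a + 1 - s):
                for nb in range(cap_b + 1):
                    if b > 0 and nb != cap_b:
                        continue
                    if q > 0 and s + b != cap_a:
                        continue
                    states.append((q, s, b, nb))
    if len(states) > max_states:
        raise ValueError(
            f"state space of {len(states)} exceeds {max_states}; shrink the instance"
        )
    index = {st: i for i, st in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))

    def add(src, dst, rate):
        i, j = index[src], index[dst]
        Q[i, j] += rate
        Q[i, i] -= rate

    for q, s, b, nb in states:
        st = (q, s, b, nb)
        # arrival
        if s + b < cap_a:
            add(st, (q, s + 1, b, nb), lam)
        elif q < queue_cap:
            add(st, (q + 1, s, b, nb), lam)
        # (else: lost / queue full -- no transition)
        # service completion in A
        if s > 0:
            if nb < cap_b:  # move to B; freed A bed pulls from queue
                dst = (q - 1, s, b, nb + 1) if q > 0 else (q, s - 1, b, nb + 1)
                add(st, dst, s * mu_a)
            else:  # B full: becomes blocked, still holds the A bed
                add(st, (q, s - 1, b + 1, nb), s * mu_a)
        # departure from B
        if nb > 0:
            if b > 0:  # instant transfer of a blocked patient; A bed freed
                dst = (q - 1, s + 1, b - 1, nb) if q > 0 else (q, s, b - 1, nb)
            else:
                dst = (q, s, b, nb - 1)
            add(st, dst, nb * mu_b)

    # global balance pi Q = 0 with normalisation
    A = np.vstack([Q.T, np.ones(n)])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    occ_a = np.zeros(cap_a + 1)
    occ_b = np.zeros(cap_b + 1)
    p_blocked = p_full = mean_q = 0.0
    for (q, s, b, nb), p in zip(states, pi):
        occ_a[s + b] += p
        occ_b[nb] += p
        mean_q += q * p
        if b > 0:
            p_blocked += p
        if s + b == cap_a:
            p_full += p
    return TandemStationary(states, pi, occ_a, occ_b, p_blocked, p_full, mean_q)


def averages_based_beds(arrival_rate: float, mean_los: float, occupancy_target: float) -> float:
    """Deterministic averages-based bed requirement:
    arrival_rate x mean_los / occupancy_target.

    This is the familiar planning calculation whose output the flex-capacity
    analysis complements; it ignores variability and therefore understates
    the capacity needed to keep blocking rare.
    """
    if not 0 < occupancy_target <= 1:
        raise ValueError(f"occupancy_target must be in (0, 1], got {occupancy_target}")
    if not arrival_rate > 0 or not mean_los > 0:
        raise ValueError("arrival_rate and mean_los must be > 0")
    return arrival_rate * mean_los / occupancy_target
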