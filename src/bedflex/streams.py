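"""Seeded random streams and samplers.

Each replication owns a family of named substreams, one per purpose
(arrival timing, patient classification, per-unit lengths of stay, per-unit
routing), derived from ``(base_seed, replication_index, purpose name)``
through :class:`numpy.random.SeedSequence`. This gives three guarantees:

* identical seed and configuration reproduce the sample path bit-for-bit;
* substreams are statistically independent by construction, so consuming
  more LOS draws at one unit never perturbs the arrival sequence;
* per-patient draws are indexed by patient id, not by the order in which the
  simulation happens to request them. Patient *i*'s LOS at unit *u* is a
  fixed function of the seed, so coupled sample paths under common random
  numbers survive capacity changes — the basis of the monotonicity checks
  and of low-variance scenario comparison.

LOS values are produced by inverse-CDF transform of the indexed uniforms,
with the quantile functions evaluated in vectorised blocks.
"""

from __future__ import annotations

import zlib
from typing import Callable, Sequence

import numpy as np
from scipy import special

from .config import LOSSpec, RouteSpec

__all__ = [
    "ReplicationStreams",
    "IndexedUniforms",
    "los_ppf",
    "make_los_sampler",
    "sample_interarrival",
    "choose_route",
]

_BLOCK = 1024


def _substream(base_seed: int, replication_index: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(
        entropy=(int(base_seed) & 0xFFFFFFFF, int(replication_index)), spawn_key=(key,)
    )
    return np.random.Generator(np.random.PCG64(ss))


def los_ppf(spec: LOSSpec, u: np.ndarray) -> np.ndarray:
    """Quantile function of the LOS distribution, vectorised over ``u``."""
    u = np.asarray(u, dtype=float)
    p = spec.native_params()
    if spec.family == "exponential":
        return -p["scale"] * np.log1p(-u)
    if spec.family == "fixed":
        return np.full_like(u, p["value"])
    if spec.family == "lognormal":
        return np.exp(p["mu"] + p["sigma"] * special.ndtri(u))
    if spec.family == "gamma":
        return special.gammaincinv(p["shape"], u) * p["scale"]
    raise ValueError(f"unsupported LOS family {spec.family!r}")


class IndexedUniforms:
    """Uniform(0,1) draws addressable by integer index, grown in blocks."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._buf = np.empty(0)

    def get(self, i: int) -> float:
        if i >= self._buf.size:
            need = max(i + 1 - self._buf.size, _BLOCK)
            self._buf = np.concatenate([self._buf, self._rng.random(need)])
        return float(self._buf[i])

    def block(self, n: int) -> np.ndarray:
        """First ``n`` draws as an array (for vectorised transforms)."""
        if n > self._buf.size:
            self._buf = np.concatenate([self._buf, self._rng.random(n - self._buf.size)])
        return self._buf[:n]


class IndexedLOS:
    """Per-patient LOS values: inverse-CDF transform of indexed uniforms."""

    def __init__(self, spec: LOSSpec, rng: np.random.Generator):
        self._spec = spec
        self._uniforms = IndexedUniforms(rng)
        self._vals = np.empty(0)

    def get(self, i: int) -> float:
        if i >= self._vals.size:
            n = max(i + 1, self._vals.size + _BLOCK)
            self._vals = los_ppf(self._spec, self._uniforms.block(n))
        return float(self._vals[i])


class ReplicationStreams:
    """All random streams for one replication.

    Substreams are named; the derivation is a pure function of
    ``(base_seed, replication_index, name)``, so adding units or purposes
    never disturbs existing streams.
    """

    def __init__(self, base_seed: int, replication_index: int = 0):
        self.base_seed = int(base_seed)
        self.replication_index = int(replication_index)
        self._cache: dict[str, object] = {}

    def generator(self, name: str) -> np.random.Generator:
        key = f"gen:{name}"
        if key not in self._cache:
            self._cache[key] = _substream(self.base_seed, self.replication_index, name)
        return self._cache[key]  # type: ignore[return-value]

    def uniforms(self, name: str) -> IndexedUniforms:
        key = f"unif:{name}"
        if key not in self._cache:
            self._cache[key] = IndexedUniforms(
                _substream(self.base_seed, self.replication_index, name)
            )
        return self._cache[key]  # type: ignore[return-value]

    def los(self, unit: str, klass: str, spec: LOSSpec) -> IndexedLOS:
        key = f"los:{unit}:{klass}"
        if key not in self._cache:
            self._cache[key] = IndexedLOS(
                spec, _substream(self.base_seed, self.replication_index, f"los:{unit}:{klass}")
            )
        return self._cache[key]  # type: ignore[return-value]


def sample_interarrival(rng: np.random.Generator, rate: float) -> float:
    """One exponential inter-arrival time (days) of a Poisson process."""
    if not rate > 0:
        raise ValueError(f"arrival rate must be > 0, got {rate}")
    return float(rng.exponential(1.0 / rate))


def make_los_sampler(spec: LOSSpec, rng: np.random.Generator) -> Callable[[], float]:
    """Sequential LOS sampler for ``spec`` (fixed family returns the constant
    exactly; stochastic families are sampled by inverse CDF)."""
    if spec.family not in ("exponential", "lognormal", "gamma", "fixed"):
        raise ValueError(f"unsupported LOS family {spec.family!r}")
    if spec.family == "fixed":
        value = spec.mean
        return lambda: value
    return lambda: float(los_ppf(spec, rng.random()))


def choose_route(rng_or_u, routes: Sequence[RouteSpec]) -> RouteSpec:
    """Select a route with the configured probabilities.

    ``rng_or_u`` is either a Generator or a pre-drawn uniform in [0, 1).
    Deterministic when a single route has probability 1.
    """
    if not routes:
        raise ValueError("cannot route from a unit with no routes configured")
    u = rng_or_u if isinstance(rng_or_u, float) else float(rng_or_u.random())
    acc = 0.0
    for r in routes:
        acc += r.probability
        if u < acc:
            return r
    return routes[-1]  # guard against probabilities summing to 1 - eps
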