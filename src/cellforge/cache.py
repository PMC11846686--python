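"""Cache-update schedules for accelerated reverse-process inference.

The schedule is the ordered step set xi = {p_1, ..., p_m} at which the full
backbone runs and the deep feature is refreshed; every other reverse step
takes the truncated cached pass.  The first reverse step T-1 is always in
xi, since a cached pass needs a feature to exist.  A fixed interval c gives
the arithmetic progression {T-1, T-1-c, ...} (the "skipping step size" of
the sampler, default 5); dynamic schedules cycle a list of intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CacheConfigError(ValueError):
    """Invalid cache-schedule parameters."""


@dataclass(frozen=True)
class CacheSchedule:
    """Update-step set xi over T reverse steps, with cache depth b."""

    T: int
    xi: frozenset[int]
    depth: int = 2
    interval: int | None = None

    def __post_init__(self) -> None:
        if self.T < 1:
            raise CacheConfigError("T must be >= 1")
        if not self.xi:
            raise CacheConfigError("xi must be non-empty")
        if (self.T - 1) not in self.xi:
            raise CacheConfigError("the first reverse step T-1 must be in xi")
        if min(self.xi) < 0 or max(self.xi) > self.T - 1:
            raise CacheConfigError("xi indices must lie in [0, T-1]")

    @property
    def n_updates(self) -> int:
        return len(self.xi)

    def steps(self) -> list[int]:
        """Update steps sorted descending (reverse-process order)."""
        return sorted(self.xi, reverse=True)


def make_cache_schedule(T: int, interval: int, depth: int = 2) -> CacheSchedule:
    """Fixed-interval schedule xi = {T-1, T-1-c, T-1-2c, ...}."""
    if interval < 1:
        raise CacheConfigError("interval c must be >= 1")
    if interval > T:
        raise CacheConfigError("interval c must be <= T")
    xi = frozenset(range(T - 1, -1, -interval))
    return CacheSchedule(T=T, xi=xi, depth=depth, interval=interval)


def make_dynamic_schedule(T: int, intervals: list[int],
                          depth: int = 2) -> CacheSchedule:
    """Dynamic schedule: consecutive gaps cycle through ``intervals``."""
    if not intervals:
        raise CacheConfigError("need at least one interval")
    if any(c < 1 for c in intervals):
        raise CacheConfigError("intervals must be positive")
    steps = [T - 1]
    i = 0
    while steps[-1] - intervals[i % len(intervals)] >= 0:
        steps.append(steps[-1] - intervals[i % len(intervals)])
        i += 1
    return CacheSchedule(T=T, xi=frozenset(steps), depth=depth, interval=None)


def should_update(s: CacheSchedule, t: int) -> bool:
    """True iff the full backbone runs (and the cache refreshes) at step t."""
    if not (0 <= t <= s.T - 1):
        raise ValueError(f"t={t} outside [0, {s.T - 1}]")
    return t in s.xi
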