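"""Extinction-regime schedules.

A schedule maps a run horizon to the ordered list of generations at which an
extinction event strikes.  Three regimes are supported:

``none``
    no events, ever (the Control condition);
``fixed``
    events at every multiple of ``interval`` up to the horizon;
``random_uniform``
    event-to-event gaps drawn independently and uniformly from the inclusive
    integer range ``[min_interval, max_interval]``.

Generations are discrete, so random intervals are drawn over integers.  Events
falling beyond the horizon are dropped.  An event scheduled at generation ``g``
is applied at the start of generation ``g``, before reproduction; generation 0
never carries an event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["ExtinctionSchedule", "event_generations"]

_VARIANTS = ("none", "fixed", "random_uniform")


@dataclass(frozen=True)
class ExtinctionSchedule:
    """Specification of an extinction regime.

    Parameters
    ----------
    variant:
        One of ``"none"``, ``"fixed"``, ``"random_uniform"``.
    interval:
        Fixed gap between events (``fixed`` variant only).
    min_interval, max_interval:
        Inclusive bounds of the uniform gap distribution
        (``random_uniform`` variant only).
    """

    variant: str = "none"
    interval: int | None = None
    min_interval: int | None = None
    max_interval: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ConfigurationError(
                f"unknown schedule variant {self.variant!r}; expected one of {_VARIANTS}"
            )
        if self.variant == "fixed":
            if self.interval is None or self.interval < 1:
                raise ConfigurationError("fixed schedule requires interval >= 1")
        if self.variant == "random_uniform":
            if self.min_interval is None or self.max_interval is None:
                raise ConfigurationError(
                    "random_uniform schedule requires min_interval and max_interval"
                )
            if self.min_interval < 1:
                raise ConfigurationError("min_interval must be >= 1")
            if self.min_interval > self.max_interval:
                raise ConfigurationError("min_interval must not exceed max_interval")

    @classmethod
    def none(cls) -> "ExtinctionSchedule":
        return cls("none")

    @classmethod
    def fixed(cls, interval: int) -> "ExtinctionSchedule":
        return cls("fixed", interval=int(interval))

    @classmethod
    def random_uniform(cls, min_interval: int, max_interval: int) -> "ExtinctionSchedule":
        return cls(
            "random_uniform",
            min_interval=int(min_interval),
            max_interval=int(max_interval),
        )


def event_generations(
    schedule: ExtinctionSchedule, horizon: int, rng: np.random.Generator | None = None
) -> list[int]:
    """Return the sorted generations in ``[1, horizon]`` at which events occur.

    The ``random_uniform`` variant consumes ``rng``; the others are
    deterministic.  Gaps are measured event-to-event, the first gap from
    generation 0.
    """
    if horizon < 1:
        raise ConfigurationError("horizon must be >= 1")
    if schedule.variant == "none":
        return []
    if schedule.variant == "fixed":
        k = schedule.interval
        return list(range(k, horizon + 1, k))
    if rng is None:
        raise ConfigurationError("random_uniform schedule requires an rng")
    events: list[int] = []
    g = 0
    while True:
        g += int(rng.integers(schedule.min_interval, schedule.max_interval + 1))
        if g > horizon:
            break
        events.append(g)
    return events
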