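"""The limited-capacity niche model of evolving evolvability.

Organisms live on a discrete toroidal grid of niches.  Each organism carries a
single heritable trait, *evolvability*: the probability that an offspring
shifts to a neighbouring niche.  Every generation each organism is replaced by
a fixed number of offspring (non-overlapping generations); each niche supports
at most ``niche_capacity`` organisms, with offspring born inside a niche
taking priority over immigrants mutating in from neighbours.  Mass-extinction
events wipe every occupied niche except a few spared at random, after which
the survivors re-radiate through the vacated grid.

The population-level consequence is the object of study: lineages that spread
through more niches own a larger share of the spared ones, so repeated
indiscriminate extinctions select indirectly for higher evolvability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from ._kernel import Workspace
from .errors import ConfigurationError, EmptyPopulationError
from .schedule import ExtinctionSchedule, event_generations

__all__ = [
    "Organism",
    "SimulationConfig",
    "Population",
    "RunResult",
    "seed_population",
    "mutate_niche",
    "make_offspring",
    "enforce_capacity",
    "step_generation",
    "apply_extinction",
    "run_simulation",
]


class Organism(NamedTuple):
    """A niche coordinate on the torus plus a heritable niche-shift probability."""

    niche_x: int
    niche_y: int
    evolvability: float


@dataclass(frozen=True)
class SimulationConfig:
    """All model parameters and the extinction regime for one run.

    Defaults are the full-scale study conditions: a 401x401 toroidal grid
    seeded with a single founder of evolvability 0.025, two offspring per
    parent, evolvability mutated with probability 0.005 by a perturbation
    uniform on [-0.0025, +0.0025], run for 15000 generations, extinctions
    sparing 5 occupied niches.  ``niche_capacity`` bounds the number of
    organisms a niche supports (default 10).
    """

    grid_width: int = 401
    grid_height: int = 401
    niche_capacity: int = 10
    offspring_per_parent: int = 2
    initial_evolvability: float = 0.025
    evolvability_mutation_rate: float = 0.005
    evolvability_perturbation_half_width: float = 0.0025
    generations: int = 15000
    extinction_schedule: ExtinctionSchedule = field(default_factory=ExtinctionSchedule.none)
    severity: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_width < 1 or self.grid_height < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if self.niche_capacity < 1:
            raise ConfigurationError("niche_capacity must be >= 1")
        if self.offspring_per_parent < 1:
            raise ConfigurationError("offspring_per_parent must be >= 1")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if self.severity < 1:
            raise ConfigurationError("severity must be >= 1")
        for name in ("initial_evolvability", "evolvability_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.evolvability_perturbation_half_width < 0.0:
            raise ConfigurationError("evolvability_perturbation_half_width must be >= 0")

    @property
    def founder_niche(self) -> tuple[int, int]:
        """Centre cell of the grid (floor convention for even dimensions)."""
        return self.grid_width // 2, self.grid_height // 2


class Population:
    """The organisms alive at one generation, as parallel coordinate arrays.

    Organisms are stored column-wise (``niche_x``, ``niche_y``,
    ``evolvability``) for speed; :meth:`organisms` iterates them as
    :class:`Organism` records.
    """

    __slots__ = ("niche_x", "niche_y", "evolvability", "generation", "grid_width", "grid_height")

    def __init__(
        self,
        niche_x: np.ndarray,
        niche_y: np.ndarray,
        evolvability: np.ndarray,
        grid_width: int,
        grid_height: int,
        generation: int = 0,
    ):
        self.niche_x = np.asarray(niche_x, dtype=np.int64)
        self.niche_y = np.asarray(niche_y, dtype=np.int64)
        self.evolvability = np.asarray(evolvability, dtype=np.float64)
        if not (len(self.niche_x) == len(self.niche_y) == len(self.evolvability)):
            raise ValueError("population columns must have equal length")
        self.grid_width = int(grid_width)
        self.grid_height = int(grid_height)
        self.generation = int(generation)

    @classmethod
    def from_organisms(
        cls,
        organisms: Iterable[Organism | tuple[int, int, float]],
        grid_width: int,
        grid_height: int,
        generation: int = 0,
    ) -> "Population":
        orgs = [Organism(*o) for o in organisms]
        return cls(
            np.array([o.niche_x for o in orgs], dtype=np.int64),
            np.array([o.niche_y for o in orgs], dtype=np.int64),
            np.array([o.evolvability for o in orgs], dtype=np.float64),
            grid_width,
            grid_height,
            generation,
        )

    def __len__(self) -> int:
        return len(self.niche_x)

    def organisms(self) -> Iterator[Organism]:
        for x, y, e in zip(self.niche_x, self.niche_y, self.evolvability):
            yield Organism(int(x), int(y), float(e))

    def niche_ids(self) -> np.ndarray:
        """Flat niche index ``y * grid_width + x`` per organism."""
        return self.niche_y * self.grid_width + self.niche_x

    def copy(self) -> "Population":
        return Population(
            self.niche_x.copy(),
            self.niche_y.copy(),
            self.evolvability.copy(),
            self.grid_width,
            self.grid_height,
            self.generation,
        )

    def validate(self, niche_capacity: int | None = None) -> None:
        """Raise if any invariant (bounds, capacity) is violated."""
        if len(self) and (
            self.niche_x.min() < 0
            or self.niche_x.max() >= self.grid_width
            or self.niche_y.min() < 0
            or self.niche_y.max() >= self.grid_height
        ):
            raise ValueError("niche coordinate outside the grid")
        if len(self) and (self.evolvability.min() < 0.0 or self.evolvability.max() > 1.0):
            raise ValueError("evolvability outside [0, 1]")
        if niche_capacity is not None and len(self):
            counts = np.unique(self.niche_ids(), return_counts=True)[1]
            if counts.max() > niche_capacity:
                raise ValueError("niche over capacity")


@dataclass
class RunResult:
    """Per-generation time series and final state of one simulation run.

    The series have ``generations + 1`` entries; index 0 is the founder state.
    ``extinction_events`` lists the generations at which an event was applied,
    and ``post_extinction_occupied`` the occupied-niche count immediately
    after each event (before that generation's reproduction).
    """

    avg_evolvability: np.ndarray
    occupied_niches: np.ndarray
    population_size: np.ndarray
    extinction_events: list[int]
    post_extinction_occupied: list[int]
    final_population: Population
    config: SimulationConfig
    snapshots: dict[int, Population] = field(default_factory=dict)

    @property
    def generations(self) -> np.ndarray:
        return np.arange(len(self.avg_evolvability))

    def to_frame(self):
        """Time series as a pandas DataFrame (one row per generation)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": self.generations,
                "avg_evolvability": self.avg_evolvability,
                "occupied_niches": self.occupied_niches,
                "population_size": self.population_size,
            }
        )


def seed_population(config: SimulationConfig) -> Population:
    """Found the population: one ancestral organism at the grid centre."""
    cx, cy = config.founder_niche
    return Population(
        np.array([cx], dtype=np.int64),
        np.array([cy], dtype=np.int64),
        np.array([config.initial_evolvability], dtype=np.float64),
        config.grid_width,
        config.grid_height,
        generation=0,
    )


def mutate_niche(
    coord: tuple[int, int],
    grid_shape: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Shift a niche one unit in a uniformly chosen cardinal direction.

    Coordinates wrap toroidally; the four moves (+x, -x, +y, -y) are
    equiprobable.
    """
    x, y = coord
    width, height = grid_shape
    d = int(rng.random() * 4.0)
    if d == 0:
        x = (x + 1) % width
    elif d == 1:
        x = (x - 1) % width
    elif d == 2:
        y = (y + 1) % height
    else:
        y = (y - 1) % height
    return x, y


def make_offspring(
    parent: Organism, config: SimulationConfig, rng: np.random.Generator
) -> Organism:
    """Produce one offspring of ``parent``.

    The offspring shifts niche with probability equal to the parent's
    evolvability, and its inherited evolvability is perturbed by
    ``Uniform(-h, +h)`` with probability ``evolvability_mutation_rate``
    (independent draws), clamped to [0, 1].
    """
    x, y = parent.niche_x, parent.niche_y
    if rng.random() < parent.evolvability:
        x, y = mutate_niche((x, y), (config.grid_width, config.grid_height), rng)
    e = parent.evolvability
    if rng.random() < config.evolvability_mutation_rate:
        h = config.evolvability_perturbation_half_width
        e = min(1.0, max(0.0, e + rng.uniform(-h, h)))
    return Organism(x, y, e)


def enforce_capacity(
    offspring: Sequence[Organism],
    resident: Sequence[bool],
    capacity: int,
    rng: np.random.Generator,
) -> list[Organism]:
    """Cull candidate offspring down to ``capacity`` per niche.

    ``resident[i]`` tags whether offspring ``i``'s parent occupied its
    destination niche.  Residents are admitted first: if they overflow, a
    uniform random subset of residents of size ``capacity`` survives and all
    immigrants to that niche are discarded; otherwise immigrants fill the
    remaining slots, the excess discarded uniformly at random.
    """
    if capacity < 1:
        raise ConfigurationError("capacity must be >= 1")
    if len(offspring) != len(resident):
        raise ValueError("offspring and resident tags must align")
    by_niche: dict[tuple[int, int], tuple[list[int], list[int]]] = {}
    for i, (org, res) in enumerate(zip(offspring, resident)):
        groups = by_niche.setdefault((org.niche_x, org.niche_y), ([], []))
        groups[0 if res else 1].append(i)
    survivors: list[Organism] = []
    for residents, immigrants in by_niche.values():
        if len(residents) > capacity:
            keep = rng.choice(len(residents), size=capacity, replace=False)
            survivors.extend(offspring[residents[j]] for j in sorted(keep))
            continue
        survivors.extend(offspring[i] for i in residents)
        room = capacity - len(residents)
        if len(immigrants) > room:
            keep = rng.choice(len(immigrants), size=room, replace=False)
            survivors.extend(offspring[immigrants[j]] for j in sorted(keep))
        else:
            survivors.extend(offspring[i] for i in immigrants)
    return survivors


def _as_buffers(pop: Population, config: SimulationConfig):
    """Copy a population into kernel-sized int32/float64 working arrays."""
    max_pop = config.grid_width * config.grid_height * config.niche_capacity
    x = np.empty(max_pop, np.int32)
    y = np.empty(max_pop, np.int32)
    e = np.empty(max_pop, np.float64)
    n = len(pop)
    x[:n] = pop.niche_x
    y[:n] = pop.niche_y
    e[:n] = pop.evolvability
    return x, y, e, n


def step_generation(
    pop: Population, config: SimulationConfig, rng: np.random.Generator
) -> Population:
    """Advance the population one generation (reproduction + capacity cull)."""
    if len(pop) == 0:
        raise EmptyPopulationError("cannot step an empty population")
    ws = Workspace(
        config.grid_width, config.grid_height, config.niche_capacity, config.offspring_per_parent
    )
    x, y, e, n = _as_buffers(pop, config)
    n, _ = ws.step(
        x,
        y,
        e,
        n,
        config.grid_width,
        config.grid_height,
        config.niche_capacity,
        config.offspring_per_parent,
        config.evolvability_mutation_rate,
        config.evolvability_perturbation_half_width,
        rng,
    )
    return Population(
        x[:n].astype(np.int64),
        y[:n].astype(np.int64),
        e[:n].copy(),
        config.grid_width,
        config.grid_height,
        pop.generation + 1,
    )


def apply_extinction(
    pop: Population, severity: int, rng: np.random.Generator
) -> Population:
    """Spare ``severity`` occupied niches chosen uniformly; empty the rest.

    If no more than ``severity`` niches are occupied the population is
    returned unchanged (sparing cannot remove anything).
    """
    if len(pop) == 0:
        raise EmptyPopulationError("cannot apply an extinction to an empty population")
    ids = pop.niche_ids()
    occupied = np.unique(ids)
    if len(occupied) <= severity:
        return pop
    spared = rng.choice(occupied, size=severity, replace=False)
    mask = np.isin(ids, spared)
    return Population(
        pop.niche_x[mask],
        pop.niche_y[mask],
        pop.evolvability[mask],
        pop.grid_width,
        pop.grid_height,
        pop.generation,
    )


def run_simulation(
    config: SimulationConfig,
    snapshot_generations: Sequence[int] = (),
    progress_interval: int | None = None,
) -> RunResult:
    """Run the model for ``config.generations`` generations.

    The run RNG is seeded from ``config.rng_seed`` and consumed in a fixed
    order (schedule intervals first, then per generation: extinction sparing
    if scheduled, then the reproduction/cull step), so results are fully
    reproducible.  ``snapshot_generations`` requests full population
    snapshots at the named generations (the final population is always
    kept).  With ``progress_interval`` set, a progress line (generation,
    population size, occupied niches) is printed every that many
    generations, and every extinction event is reported as it strikes.
    """
    rng = np.random.default_rng(config.rng_seed)
    horizon = config.generations
    events = event_generations(config.extinction_schedule, horizon, rng)
    event_set = set(events)
    wanted_snapshots = set(int(g) for g in snapshot_generations)

    pop = seed_population(config)
    ws = Workspace(
        config.grid_width, config.grid_height, config.niche_capacity, config.offspring_per_parent
    )
    x, y, e, n = _as_buffers(pop, config)

    avg = np.empty(horizon + 1)
    occ = np.empty(horizon + 1, dtype=np.int64)
    size = np.empty(horizon + 1, dtype=np.int64)
    avg[0] = config.initial_evolvability
    occ[0] = 1
    size[0] = n
    post_ext_occ: list[int] = []
    snapshots: dict[int, Population] = {}
    if 0 in wanted_snapshots:
        snapshots[0] = pop

    width, height = config.grid_width, config.grid_height
    for g in range(1, horizon + 1):
        if g in event_set:
            ids = y[:n].astype(np.int64) * width + x[:n]
            occupied = np.unique(ids)
            if len(occupied) > config.severity:
                spared = rng.choice(occupied, size=config.severity, replace=False)
                mask = np.isin(ids, spared)
                n = int(mask.sum())
                x[:n] = x[: len(mask)][mask]
                y[:n] = y[: len(mask)][mask]
                e[:n] = e[: len(mask)][mask]
                post_ext_occ.append(config.severity)
            else:
                post_ext_occ.append(len(occupied))
            if progress_interval is not None:
                print(
                    f"extinction at generation {g}: occupied niches -> {post_ext_occ[-1]}"
                )
        if n == 0:
            raise EmptyPopulationError(f"population extinct at generation {g}")
        n, n_occ = ws.step(
            x,
            y,
            e,
            n,
            width,
            height,
            config.niche_capacity,
            config.offspring_per_parent,
            config.evolvability_mutation_rate,
            config.evolvability_perturbation_half_width,
            rng,
        )
        avg[g] = e[:n].mean()
        occ[g] = n_occ
        size[g] = n
        if progress_interval is not None and g % progress_interval == 0:
            print(f"generation {g}: population {n}, occupied niches {n_occ}")
        if g in wanted_snapshots:
            snapshots[g] = Population(
                x[:n].astype(np.int64), y[:n].astype(np.int64), e[:n].copy(),
                width, height, generation=g,
            )

    final = Population(
        x[:n].astype(np.int64), y[:n].astype(np.int64), e[:n].copy(),
        width, height, generation=horizon,
    )
    return RunResult(
        avg_evolvability=avg,
        occupied_niches=occ,
        population_size=size,
        extinction_events=events,
        post_extinction_occupied=post_ext_occ,
        final_population=final,
        config=config,
        snapshots=snapshots,
    )
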