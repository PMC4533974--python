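"""Experimental designs: conditions, multi-run aggregation, sweeps, outputs.

A *condition* is a named simulation configuration replicated over independent
seeded runs (run ``i`` uses ``base_seed + i``).  The harness reproduces the
study designs: a Control condition with no extinctions, fixed-interval
extinction conditions, a random-interval condition, pairwise Mann-Whitney
comparisons of per-run final evolvability, the pooled evolvability-vs-distance
Spearman correlation, and a severity sweep.

Two named profiles bundle the scales used throughout the package: ``full``
(401x401 grid, 15000 generations, 50 runs — the full-scale conditions) and
``desk`` (101x101 grid, 3000 generations, 20 runs, extinction intervals
scaled 200/400/800), sized so a full condition runs in minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import Population, RunResult, SimulationConfig, run_simulation
from .schedule import ExtinctionSchedule
from .stats import (
    TestResult,
    evolvability_heatmap,
    mann_whitney_u,
    spearman_correlation,
    toroidal_distances,
)

__all__ = [
    "Profile",
    "PROFILES",
    "ConditionSpec",
    "ConditionResult",
    "make_condition",
    "run_condition",
    "compare_final_evolvability",
    "evolvability_distance_correlation",
    "saturation_generation",
    "severity_sweep",
    "read_run_series",
    "write_condition_outputs",
]


@dataclass(frozen=True)
class Profile:
    """A named scale at which the five conditions are instantiated."""

    name: str
    grid_width: int
    grid_height: int
    niche_capacity: int
    generations: int
    n_runs: int
    fixed_intervals: tuple[int, int, int]  # the three regular-interval conditions
    random_interval: tuple[int, int]

    def base_config(self, **overrides) -> SimulationConfig:
        kwargs = dict(
            grid_width=self.grid_width,
            grid_height=self.grid_height,
            niche_capacity=self.niche_capacity,
            generations=self.generations,
        )
        kwargs.update(overrides)
        return SimulationConfig(**kwargs)


PROFILES: dict[str, Profile] = {
    "full": Profile(
        name="full",
        grid_width=401,
        grid_height=401,
        niche_capacity=10,
        generations=15000,
        n_runs=50,
        fixed_intervals=(1000, 2000, 4000),
        random_interval=(1000, 4000),
    ),
    "desk": Profile(
        name="desk",
        grid_width=101,
        grid_height=101,
        niche_capacity=10,
        generations=3000,
        n_runs=20,
        fixed_intervals=(200, 400, 800),
        random_interval=(200, 800),
    ),
}


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: a config replicated over seeded runs."""

    name: str
    config: SimulationConfig
    n_runs: int
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")

    def run_seed(self, run_index: int) -> int:
        return self.base_seed + run_index


@dataclass
class ConditionResult:
    """All runs of one condition plus the cross-run aggregates."""

    spec: ConditionSpec
    runs: list[RunResult]
    mean_avg_evolvability: np.ndarray = field(init=False)
    final_avg_evolvability: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        series = np.stack([r.avg_evolvability for r in self.runs])
        self.mean_avg_evolvability = series.mean(axis=0)
        self.final_avg_evolvability = series[:, -1].copy()

    @property
    def name(self) -> str:
        return self.spec.name

    def final_populations(self) -> list[Population]:
        return [r.final_population for r in self.runs]


def make_condition(
    name: str,
    profile: Profile | str = "desk",
    schedule: ExtinctionSchedule | None = None,
    base_seed: int = 1,
    n_runs: int | None = None,
    **config_overrides,
) -> ConditionSpec:
    """Build a ConditionSpec from a named profile.

    ``schedule=None`` gives the Control condition.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    if schedule is None:
        schedule = ExtinctionSchedule.none()
    config = profile.base_config(extinction_schedule=schedule, **config_overrides)
    return ConditionSpec(
        name=name,
        config=config,
        n_runs=profile.n_runs if n_runs is None else n_runs,
        base_seed=base_seed,
    )


def run_condition(
    spec: ConditionSpec,
    snapshot_generations: Sequence[int] = (),
    progress: bool = False,
) -> ConditionResult:
    """Execute the condition's ``n_runs`` independent runs and aggregate."""
    runs: list[RunResult] = []
    for i in range(spec.n_runs):
        config = replace(spec.config, rng_seed=spec.run_seed(i))
        try:
            result = run_simulation(config, snapshot_generations=snapshot_generations)
        except Exception as exc:  # re-raise with the failing run attached
            raise RuntimeError(f"condition {spec.name!r}, run {i} failed") from exc
        runs.append(result)
        if progress:
            print(
                f"[{spec.name}] run {i + 1}/{spec.n_runs}: "
                f"final avg evolvability {result.avg_evolvability[-1]:.4f}, "
                f"occupied niches {result.occupied_niches[-1]}"
            )
    return ConditionResult(spec=spec, runs=runs)


def compare_final_evolvability(a: ConditionResult, b: ConditionResult) -> TestResult:
    """Mann-Whitney U on the two conditions' per-run final average evolvability."""
    if len(a.runs) < 2 or len(b.runs) < 2:
        raise ValueError("need at least 2 runs per condition to compare")
    return mann_whitney_u(a.final_avg_evolvability, b.final_avg_evolvability)


def evolvability_distance_correlation(
    result: ConditionResult, metric: str = "euclidean"
) -> TestResult:
    """Spearman correlation of evolvability with distance from the founder niche.

    Organisms from all runs' final populations are pooled; each organism
    contributes its evolvability and the toroidal distance of its niche from
    the founding (centre) niche.
    """
    origin = result.spec.config.founder_niche
    shape = (result.spec.config.grid_width, result.spec.config.grid_height)
    dists = []
    evols = []
    for pop in result.final_populations():
        dists.append(toroidal_distances(pop.niche_x, pop.niche_y, origin, shape, metric))
        evols.append(pop.evolvability)
    return spearman_correlation(np.concatenate(dists), np.concatenate(evols))


def saturation_generation(occupied_series: np.ndarray, window: int = 100) -> int:
    """First generation after which the occupied-niche count stops growing.

    Returns the smallest ``g`` such that the count is unchanged for the next
    ``window`` consecutive generations.  Raises if no such plateau exists
    within the series.
    """
    occ = np.asarray(occupied_series)
    for g in range(len(occ) - window):
        if occ[g + window] == occ[g] and np.all(occ[g : g + window + 1] == occ[g]):
            return g
    raise ValueError(f"no {window}-generation plateau in the occupied-niche series")


def severity_sweep(
    base: ConditionSpec, severities: Sequence[int], seed_stride: int = 100_000
) -> dict[int, ConditionResult]:
    """Run the base condition once per severity, all else held fixed.

    Severity ``severities[i]`` uses base seed ``base.base_seed + i * seed_stride``
    so the sweep's runs are mutually independent; the first severity reuses
    the base seed unchanged.
    """
    results: dict[int, ConditionResult] = {}
    for i, sev in enumerate(severities):
        if sev < 1:
            raise ConfigurationError("severity must be >= 1")
        spec = ConditionSpec(
            name=f"{base.name}_severity{sev}",
            config=replace(base.config, severity=int(sev)),
            n_runs=base.n_runs,
            base_seed=base.base_seed + i * seed_stride,
        )
        results[int(sev)] = run_condition(spec)
    return results


def read_run_series(path) -> pd.DataFrame:
    """Read a per-run time-series CSV back, bit-exact.

    Uses the round-trip float parser so the shortest-repr floats written by
    :func:`write_condition_outputs` reconstruct the in-memory series exactly.
    """
    return pd.read_csv(path, float_precision="round_trip")


def write_condition_outputs(
    result: ConditionResult,
    out_dir,
    snapshot_generations: Sequence[int] | None = None,
) -> list[Path]:
    """Write a condition's outputs to ``out_dir``; returns the paths written.

    Per-run time-series CSVs (``generation,avg_evolvability,occupied_niches,
    population_size``), the pooled final-population CSV
    (``niche_x,niche_y,evolvability``), heatmap TSVs of the first
    (representative) run at each requested snapshot generation, and a JSON
    summary holding the per-run final averages and the extinction log.
    Identical inputs re-emit bit-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    horizon = result.spec.config.generations
    if snapshot_generations is None:
        snapshot_generations = [g for g in (2000, horizon) if g <= horizon]

    for i, run in enumerate(result.runs):
        path = out / f"run_{i:03d}.csv"
        run.to_frame().to_csv(path, index=False)
        written.append(path)

    pooled = pd.concat(
        [
            pd.DataFrame(
                {
                    "niche_x": pop.niche_x,
                    "niche_y": pop.niche_y,
                    "evolvability": pop.evolvability,
                }
            )
            for pop in result.final_populations()
        ],
        ignore_index=True,
    )
    pooled_path = out / "final_population.csv"
    pooled.to_csv(pooled_path, index=False)
    written.append(pooled_path)

    rep = result.runs[0]
    for g in snapshot_generations:
        pop = rep.snapshots.get(int(g))
        if pop is None and int(g) == horizon:
            pop = rep.final_population
        if pop is None:
            continue
        hm_path = out / f"heatmap_gen{int(g)}.tsv"
        evolvability_heatmap(pop).to_tsv(hm_path)
        written.append(hm_path)

    summary = {
        "condition": result.name,
        "n_runs": len(result.runs),
        "generations": horizon,
        "final_avg_evolvability": [float(v) for v in result.final_avg_evolvability],
        "extinction_events": [list(map(int, r.extinction_events)) for r in result.runs],
    }
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(summary_path)
    return written
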