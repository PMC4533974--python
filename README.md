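# extinctsim

An agent-based simulator for studying how **mass-extinction regimes shape
the evolution of evolvability**, built for researchers in artificial life
and evolutionary dynamics.

The model is a limited-capacity niche world: organisms live on a discrete
toroidal grid whose cells ("niches") each support at most a fixed number of
individuals. An organism carries one heritable trait, its *evolvability*
`e` — the probability that an offspring shifts to a neighbouring niche.
Every generation each organism is replaced by two offspring; offspring born
inside a niche take priority over immigrants, and anything beyond capacity
is discarded, so full niches cannot be invaded. Extinction events
periodically empty every occupied niche except a few spared at random
(`severity`, default 5), after which survivors re-radiate through the vacant
grid.

Because lineages with higher `e` spread through more niches, they own a
larger share of the randomly spared ones and refill the emptied grid faster
— so repeated indiscriminate extinctions select *indirectly* for
evolvability. The package provides the simulator, the extinction-schedule
regimes (none / fixed interval / random-uniform interval), the summary
metrics (mean evolvability, niche occupancy, evolvability heatmaps, rebound
magnitude), self-contained Mann-Whitney U and Spearman rank statistics, and
an experiment harness that replicates the study designs (multi-run
conditions, severity sweeps, evolvability-vs-distance correlations).

## A worked example

```python
import extinctsim as xs

config = xs.SimulationConfig(
    grid_width=51, grid_height=51, niche_capacity=10, generations=600,
    extinction_schedule=xs.ExtinctionSchedule.fixed(150), severity=5,
    rng_seed=42,
)
result = xs.run_simulation(config)
print(result.extinction_events)              # [150, 300, 450, 600]
print(round(result.avg_evolvability[-1], 5)) # 0.02396
```

`python examples/single_run.py` extends this run with a commentary trace:
occupied niches collapse to ≤ 5 at each event and rebound within tens of
generations, with the rebounds growing across events (+24, +29, +37 niches
after the first three). A single run is noisy — the systematic rise in
evolvability is an ensemble effect, which
`python examples/extinction_vs_control.py` shows directly: over 10 replicate
runs of 2500 generations the extinction regime's per-run final average
evolvabilities (mean 0.0309) sit entirely above Control's (mean 0.0248),

```
Mann-Whitney U = 100.0, two-sided p = 0.0001827 (n = 10 vs 10 runs)
extinction mean - control mean = +0.0062
```

i.e. complete separation of the two conditions. The other scripts show the
severity sweep (`severity_sweep.py`: every extinction regime ends well
above Control, the effect shrinking as sparing becomes generous) and the
spatial signature (`distance_correlation.py`: evolvability correlates
positively with distance from the founding niche in Control, overwhelmingly
significant at the pooled sample size, while extinction regimes leave only
a small correlation of unstable sign).

A thin CLI wraps the same library calls:

```sh
extinctsim run --config config.toml --out out/
extinctsim experiment --condition ext_fixed --interval 200 --profile desk --out out/
extinctsim stats --summary a/summary.json --summary b/summary.json
extinctsim sweep-severity --severities 5,25,125 --interval 200 --out out/
```

## Layout

- `src/extinctsim/` — the library: `model` (organisms, populations, the
  generation step, extinctions), `schedule` (extinction regimes), `stats`
  (metrics and rank tests), `experiments` (conditions, sweeps, outputs),
  `config` (TOML round-trip), `cli`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — the model, its assumptions, parameter meanings,
  design choices and known limitations.
- `tests/` — unit, property and end-to-end suites.
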