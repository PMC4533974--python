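"""Evolvability vs distance from the founding niche, with and without extinctions.

Without extinctions, more evolvable lineages radiate farther from the
founding (centre) niche, so evolvability correlates positively with toroidal
distance from the origin in the final population.  Extinction events
repeatedly bottleneck the population at random grid locations, scrambling
that spatial signature: the pooled correlation collapses toward zero.
"""

import extinctsim as xs

profile = xs.Profile(
    name="example",
    grid_width=51,
    grid_height=51,
    niche_capacity=10,
    generations=2000,
    n_runs=6,
    fixed_intervals=(125, 250, 500),
    random_interval=(125, 500),
)

for name, schedule in [
    ("control", None),
    ("ext_125", xs.ExtinctionSchedule.fixed(125)),
]:
    condition = xs.run_condition(xs.make_condition(name, profile, schedule=schedule, base_seed=1))
    corr = xs.evolvability_distance_correlation(condition)
    print(
        f"{name:>8s}: pooled Spearman r = {corr.statistic:+.4f}, "
        f"p = {corr.p_value:.3g} over {corr.n1} organisms"
    )
print(
    "\nControl keeps a consistently positive correlation (overwhelming p at\n"
    "this pooled n); under extinctions the correlation is small with an\n"
    "unstable sign - the random bottlenecks erase the spatial trace of\n"
    "evolvable lineages' radiation from the founding niche."
)
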