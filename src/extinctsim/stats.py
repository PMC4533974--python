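"""Summary metrics over populations and runs, and nonparametric tests.

The two rank tests (Mann-Whitney U, Spearman rank correlation) are
implemented here from first principles — mid-rank tie handling, exact
small-sample enumeration for U, and the usual large-sample approximations —
so that the package's statistical claims do not depend on any statistics
library's conventions.  scipy supplies only the t and normal distribution
functions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Sequence

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist

from .errors import EmptyPopulationError, UndefinedStatisticError
from .model import Population, RunResult

__all__ = [
    "HeatmapGrid",
    "TestResult",
    "average_evolvability",
    "occupied_niche_count",
    "evolvability_heatmap",
    "toroidal_distance",
    "midranks",
    "spearman_correlation",
    "mann_whitney_u",
    "rebound_magnitude",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test: the statistic, its p-value and sample sizes.

    ``statistic`` is U (of the first sample) for Mann-Whitney and r for
    Spearman; for one-sample statistics ``n2`` is None.
    """

    statistic: float
    p_value: float
    n1: int
    n2: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HeatmapGrid:
    """Per-niche mean evolvability over the grid; NaN marks empty niches.

    ``values`` has shape ``(grid_height, grid_width)`` with row = niche_y.
    """

    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def occupied_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_tsv(self, path) -> None:
        """Write as a TSV matrix, empty cells as ``NA``."""
        with open(path, "w") as fh:
            for row in self.values:
                fh.write(
                    "\t".join("NA" if np.isnan(v) else repr(float(v)) for v in row) + "\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "HeatmapGrid":
        rows = []
        with open(path) as fh:
            for line in fh:
                rows.append(
                    [np.nan if tok == "NA" else float(tok) for tok in line.rstrip("\n").split("\t")]
                )
        return cls(np.array(rows, dtype=np.float64))

    def plot(self, ax=None, **imshow_kwargs):
        """Render with matplotlib (optional dependency); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.values, origin="lower", **imshow_kwargs)
        ax.figure.colorbar(im, ax=ax, label="mean evolvability")
        return ax


def average_evolvability(pop: Population) -> float:
    """Arithmetic mean evolvability of all organisms in the population."""
    if len(pop) == 0:
        raise EmptyPopulationError("average evolvability of an empty population")
    return float(pop.evolvability.mean())


def occupied_niche_count(pop: Population) -> int:
    """Number of niches holding at least one organism."""
    if len(pop) == 0:
        return 0
    return int(len(np.unique(pop.niche_ids())))


def evolvability_heatmap(
    pop: Population, grid_shape: tuple[int, int] | None = None
) -> HeatmapGrid:
    """Mean evolvability per niche; unoccupied niches are NaN."""
    if grid_shape is None:
        grid_shape = (pop.grid_width, pop.grid_height)
    width, height = grid_shape
    sums = np.zeros((height, width))
    counts = np.zeros((height, width), dtype=np.int64)
    np.add.at(sums, (pop.niche_y, pop.niche_x), pop.evolvability)
    np.add.at(counts, (pop.niche_y, pop.niche_x), 1)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return HeatmapGrid(values)


def toroidal_distance(
    a: tuple[int, int],
    b: tuple[int, int],
    grid_shape: tuple[int, int],
    metric: str = "euclidean",
) -> float:
    """Distance between two niches on the torus.

    Per axis the wrapped displacement ``min(|d|, dim - |d|)`` is used;
    ``metric`` selects Euclidean (default) or Manhattan aggregation.
    """
    width, height = grid_shape
    dx = abs(int(a[0]) - int(b[0]))
    dy = abs(int(a[1]) - int(b[1]))
    dx = min(dx, width - dx)
    dy = min(dy, height - dy)
    if metric == "euclidean":
        return sqrt(dx * dx + dy * dy)
    if metric == "manhattan":
        return float(dx + dy)
    raise ValueError(f"unknown metric {metric!r}")


def toroidal_distances(
    xs: np.ndarray,
    ys: np.ndarray,
    origin: tuple[int, int],
    grid_shape: tuple[int, int],
    metric: str = "euclidean",
) -> np.ndarray:
    """Vectorised :func:`toroidal_distance` from one origin to many niches."""
    width, height = grid_shape
    dx = np.abs(np.asarray(xs, dtype=np.int64) - int(origin[0]))
    dy = np.abs(np.asarray(ys, dtype=np.int64) - int(origin[1]))
    dx = np.minimum(dx, width - dx)
    dy = np.minimum(dy, height - dy)
    if metric == "euclidean":
        return np.sqrt(dx * dx + dy * dy)
    if metric == "manhattan":
        return (dx + dy).astype(np.float64)
    raise ValueError(f"unknown metric {metric!r}")


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with tied values sharing the average of their ranks."""
    v = np.asarray(values, dtype=np.float64)
    order = np.argsort(v, kind="stable")
    sv = v[order]
    new_group = np.r_[True, sv[1:] != sv[:-1]]
    group = np.cumsum(new_group) - 1
    counts = np.bincount(group)
    ends = np.cumsum(counts)
    starts = ends - counts
    mid = (starts + ends + 1) / 2.0  # mean of ranks starts+1 .. ends
    ranks = np.empty(len(v))
    ranks[order] = mid[group]
    return ranks


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with mid-rank ties.

    r is the Pearson correlation of the mid-ranks; the two-sided p-value uses
    the t approximation with ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError("Spearman correlation needs n >= 3")
    rx = midranks(x)
    ry = midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise UndefinedStatisticError("zero rank variance: correlation undefined")
    r = float(rx @ ry) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(_t_dist.sf(abs(t), n - 2))
    return TestResult(statistic=r, p_value=min(1.0, p), n1=n, n2=None)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of the first sample, from mid-ranks of the pooled data."""
    n1, n2 = len(a), len(b)
    ranks = midranks(np.concatenate([a, b]))
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_u_pvalue(u_obs: float, n1: int, n2: int) -> float:
    """Two-sided exact p by enumerating all C(n1+n2, n1) rank labelings."""
    n = n1 + n2
    total = comb(n, n1)
    offset = n1 * (n1 + 1) / 2.0
    lo = hi = 0
    for subset in combinations(range(1, n + 1), n1):
        u = sum(subset) - offset
        if u <= u_obs:
            lo += 1
        if u >= u_obs:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The statistic is U of the first sample.  With ``method="auto"`` the
    p-value is exact (enumeration of the null distribution of U) for
    tie-free samples with ``n1 + n2 <= 12``, and otherwise uses the normal
    approximation with tie and continuity corrections; ``"exact"`` and
    ``"asymptotic"`` force one path.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise EmptyPopulationError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < n1 + n2
    u1 = _u_statistic(a, b)
    if method == "exact" or (method == "auto" and not has_ties and n1 + n2 <= 12):
        if has_ties:
            raise UndefinedStatisticError("exact Mann-Whitney p requires tie-free samples")
        p = _exact_u_pvalue(u1, n1, n2)
        return TestResult(statistic=u1, p_value=p, n1=n1, n2=n2)
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0.0:
        return TestResult(statistic=u1, p_value=1.0, n1=n1, n2=n2)
    z = (abs(u1 - mean_u) - 0.5) / sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(_norm.sf(z)))
    return TestResult(statistic=u1, p_value=p, n1=n1, n2=n2)


def rebound_magnitude(result: RunResult, extinction_generation: int, lag: int = 10) -> int:
    """Occupied-niche gain ``lag`` generations after an extinction event.

    The difference between the occupied-niche count at
    ``extinction_generation + lag`` and the count immediately after the
    event (before that generation's reproduction).
    """
    if extinction_generation not in result.extinction_events:
        raise ValueError(f"no extinction event at generation {extinction_generation}")
    horizon = len(result.avg_evolvability) - 1
    if extinction_generation + lag > horizon:
        raise ValueError("lag overruns the run horizon")
    idx = result.extinction_events.index(extinction_generation)
    after = result.post_extinction_occupied[idx]
    return int(result.occupied_niches[extinction_generation + lag]) - int(after)
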