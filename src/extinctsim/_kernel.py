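"""Numba-compiled inner loop of the generation step.

The kernel advances one non-overlapping generation in place:

1. every parent produces ``offspring_per_parent`` offspring; each offspring
   shifts to a uniformly chosen cardinal neighbour (toroidal wrap) with
   probability equal to the parent's evolvability, and its inherited
   evolvability is perturbed by ``Uniform(-h, +h)`` with probability
   ``evolvability_mutation_rate`` (independent draws), clamped to [0, 1];
2. per destination niche, offspring whose parent occupied that niche
   (residents) are admitted first, then immigrants fill any remaining slots;
   within each class a uniform random subset survives when the class
   overflows.  No niche ever exceeds ``capacity``.

Uniform subsets are obtained with reservoir sampling, so the whole step is
O(offspring).  The random stream is the ``numpy.random.Generator`` passed in
(numba shares the underlying bit-generator state with the Python side), and
draws are consumed in a fixed documented order: per offspring the shift
decision, the direction (only if shifting), the evolvability-mutation
decision, the perturbation (only if mutating); then the resident reservoir
draws in offspring order; then the immigrant reservoir draws in offspring
order.  Runs are therefore bit-reproducible from the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["Workspace", "step_kernel"]


class Workspace:
    """Preallocated buffers for repeated kernel calls on one grid.

    Population arrays are bounded by ``n_niches * capacity`` organisms and
    ``offspring_per_parent`` times that many candidate offspring.
    """

    def __init__(self, width: int, height: int, capacity: int, offspring_per_parent: int):
        n_niches = width * height
        max_pop = n_niches * capacity
        max_off = offspring_per_parent * max_pop
        self.ox = np.empty(max_off, np.int32)
        self.oy = np.empty(max_off, np.int32)
        self.oe = np.empty(max_off, np.float64)
        self.imm = np.empty(max_off, np.bool_)
        self.rcnt = np.zeros(n_niches, np.int32)
        self.scnt = np.zeros(n_niches, np.int32)
        self.icnt = np.zeros(n_niches, np.int32)
        self.slots = np.empty(n_niches * capacity, np.int32)
        self.touched = np.empty(n_niches, np.int32)
        self.nx = np.empty(max_pop, np.int32)
        self.ny = np.empty(max_pop, np.int32)
        self.ne = np.empty(max_pop, np.float64)

    def step(self, x, y, e, n, width, height, capacity, k, e_mut_rate, half_width, rng):
        """Advance one generation; survivors land in ``x/y/e[:n']``.

        Returns ``(n', occupied)``: the new population size and the number of
        occupied niches.
        """
        q, occ = step_kernel(
            x, y, e, n, width, height, capacity, k, e_mut_rate, half_width, rng,
            self.ox, self.oy, self.oe, self.imm,
            self.rcnt, self.scnt, self.icnt, self.slots, self.touched,
            self.nx, self.ny, self.ne,
        )
        x[:q] = self.nx[:q]
        y[:q] = self.ny[:q]
        e[:q] = self.ne[:q]
        return q, occ


@njit(cache=True)
def step_kernel(x, y, e, n, W, H, cap, k, p_emut, h, rng,
                ox, oy, oe, imm,
                rcnt, scnt, icnt, slots, touched,
                nx, ny, ne):  # pragma: no cover - exercised via Workspace.step
    m = k * n
    # --- reproduction with mutation -------------------------------------
    for i in range(n):
        for t in range(k):
            idx = k * i + t
            cx = x[i]
            cy = y[i]
            ce = e[i]
            if rng.random() < ce:
                d = int(rng.random() * 4.0)
                if d == 0:
                    cx = cx + 1 if cx + 1 < W else 0
                elif d == 1:
                    cx = cx - 1 if cx > 0 else W - 1
                elif d == 2:
                    cy = cy + 1 if cy + 1 < H else 0
                else:
                    cy = cy - 1 if cy > 0 else H - 1
            if rng.random() < p_emut:
                ce = ce + rng.uniform(-h, h)
                if ce < 0.0:
                    ce = 0.0
                elif ce > 1.0:
                    ce = 1.0
            ox[idx] = cx
            oy[idx] = cy
            oe[idx] = ce
            # resident iff the offspring's niche is its parent's niche
            # (a wrapped-to-self shift on a degenerate grid stays resident)
            imm[idx] = (cx != x[i]) or (cy != y[i])
    # --- capacity enforcement: residents first (reservoir sampling) ------
    nt = 0
    for i in range(m):
        if imm[i]:
            continue
        j = oy[i] * W + ox[i]
        c = rcnt[j]
        if c == 0:
            touched[nt] = j
            nt += 1
        if c < cap:
            slots[j * cap + c] = i
            scnt[j] = c + 1
        else:
            r = int(rng.random() * (c + 1))
            if r < cap:
                slots[j * cap + r] = i
        rcnt[j] = c + 1
    # --- then immigrants into the remaining slots ------------------------
    for i in range(m):
        if not imm[i]:
            continue
        j = oy[i] * W + ox[i]
        if rcnt[j] >= cap:
            continue
        if rcnt[j] == 0 and icnt[j] == 0:
            touched[nt] = j
            nt += 1
        rem = cap - scnt[j]
        c = icnt[j]
        base = scnt[j]
        if c < rem:
            slots[j * cap + base + c] = i
        else:
            r = int(rng.random() * (c + 1))
            if r < rem:
                slots[j * cap + base + r] = i
        icnt[j] = c + 1
    # --- gather survivors, grouped by niche, and reset counters ----------
    q = 0
    for t in range(nt):
        j = touched[t]
        keep = min(rcnt[j], cap)
        if rcnt[j] < cap:
            rem = cap - scnt[j]
            keep = scnt[j] + min(icnt[j], rem)
        for s in range(keep):
            i = slots[j * cap + s]
            nx[q] = ox[i]
            ny[q] = oy[i]
            ne[q] = oe[i]
            q += 1
        rcnt[j] = 0
        scnt[j] = 0
        icnt[j] = 0
    return q, nt
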