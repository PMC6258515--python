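"""Random contiguity-constrained aggregation (seed-based region growing).

``grow_regions`` partitions the ``n`` areas of a connected contiguity graph
into ``k`` spatially contiguous regions: ``k`` distinct seed areas are drawn
uniformly at random, then unassigned areas adjacent to the growing regions
are absorbed one at a time — the area uniformly at random among all feasible
ones, the receiving region uniformly at random among its assigned adjacent
regions.  On a connected graph this terminates with exactly ``k`` non-empty
connected regions.  ``dissolve_mean`` averages the attribute within regions
(the grouping operator for spatially intensive variables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sar import AreaVariable, _as_values
from .weights import SpatialWeights


@dataclass(frozen=True)
class Aggregation:
    """Contiguous k-partition of the areas; ``labels[i]`` in ``0..k-1``."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "labels", np.asarray(self.labels, dtype=np.int64)
        )

    @property
    def n(self) -> int:
        return self.labels.size

    def region_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass(frozen=True)
class AggregatedVariable:
    """Region-level variable: unweighted mean of member areas per region."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).reshape(-1)
        )

    @property
    def k(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def variance(self) -> float:
        """Population variance over the k region values (ddof=0)."""
        return float(np.var(self.values))


def grow_regions(w: SpatialWeights, k: int, seed) -> Aggregation:
    """Draw one random contiguous aggregation of ``w`` into ``k`` regions.

    Deterministic in ``(w, k, seed)``.  Raises for ``k`` outside ``1..n`` or
    a disconnected graph.
    """
    n = w.n
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if not w.is_connected():
        raise ValueError("contiguity graph must be connected")
    rng = np.random.default_rng(seed)

    labels = np.full(n, -1, dtype=np.int64)
    seeds = rng.choice(n, size=k, replace=False)
    labels[seeds] = np.arange(k)

    neighbors = w.neighbors
    # frontier: unassigned areas adjacent to >=1 assigned area, with O(1)
    # uniform removal via swap-pop
    in_frontier = np.zeros(n, dtype=bool)
    pos = np.empty(n, dtype=np.int64)
    frontier: list[int] = []
    for s in seeds:
        for nb in neighbors[s]:
            if labels[nb] < 0 and not in_frontier[nb]:
                in_frontier[nb] = True
                pos[nb] = len(frontier)
                frontier.append(nb)

    n_left = n - k
    while n_left:
        idx = int(rng.integers(len(frontier)))
        area = frontier[idx]
        last = frontier[-1]
        frontier[idx] = last
        pos[last] = idx
        frontier.pop()
        in_frontier[area] = False

        adj_regions = []
        for nb in neighbors[area]:
            lab = labels[nb]
            if lab >= 0 and lab not in adj_regions:
                adj_regions.append(lab)
        chosen = adj_regions[
            int(rng.integers(len(adj_regions))) if len(adj_regions) > 1 else 0
        ]
        labels[area] = chosen
        n_left -= 1
        for nb in neighbors[area]:
            if labels[nb] < 0 and not in_frontier[nb]:
                in_frontier[nb] = True
                pos[nb] = len(frontier)
                frontier.append(nb)
    return Aggregation(labels=labels, k=k)


def dissolve_mean(y, agg: Aggregation) -> AggregatedVariable:
    """Unweighted mean of member-area values per region."""
    yv = _as_values(y)
    if yv.size != agg.n:
        raise ValueError(
            f"variable length {yv.size} does not match partition over {agg.n} areas"
        )
    sums = np.bincount(agg.labels, weights=yv, minlength=agg.k)
    counts = np.bincount(agg.labels, minlength=agg.k)
    if np.any(counts == 0):
        raise ValueError("partition has an empty region")
    return AggregatedVariable(sums / counts)


def batch_aggregate(
    w: SpatialWeights, k: int, seed, r: int = 30
) -> list[Aggregation]:
    """``r`` independent random aggregations from counter-derived sub-seeds.

    Sub-seeds are spawned deterministically from the master seed, so the
    whole batch is reproducible and no sub-stream is reused.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    return [grow_regions(w, k, child) for child in ss.spawn(r)]


def check_contiguity(w: SpatialWeights, agg: Aggregation) -> bool:
    """True iff every region's induced subgraph is connected (BFS per region)."""
    labels = agg.labels
    seen = np.zeros(agg.n, dtype=bool)
    for region in range(agg.k):
        members = np.flatnonzero(labels == region)
        if members.size == 0:
            return False
        stack = [int(members[0])]
        seen[members[0]] = True
        count = 1
        while stack:
            a = stack.pop()
            for nb in w.neighbors[a]:
                if labels[nb] == region and not seen[nb]:
                    seen[nb] = True
                    count += 1
                    stack.append(nb)
        if count != members.size:
            return False
    return True


def _as_area_variable(y) -> AreaVariable:
    return y if isinstance(y, AreaVariable) else AreaVariable(y)
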