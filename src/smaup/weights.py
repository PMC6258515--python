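"""Contiguity structures for areal data.

A :class:`SpatialWeights` object is an undirected, symmetric contiguity graph
over ``n`` areas with 0-based contiguous area ids.  It is the ``W`` of the
spatial autoregressive process and the adjacency constraint of the random
regionalizer.  Only two sources are supported: regular rook-contiguity
lattices (built here) and GAL weights files (read/written here).  Geometry is
never consumed; adjacency is the interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


class IsolatedAreaError(ValueError):
    """An area has no neighbors, so no row-standardized view exists."""


class AsymmetricWeightsError(ValueError):
    """A GAL file lists (i, j) without (j, i)."""


@dataclass(frozen=True)
class SpatialWeights:
    """Symmetric contiguity graph over ``n`` areas (ids ``0..n-1``).

    Parameters
    ----------
    n : int
        Number of areas; must be >= 1.
    neighbors : tuple of tuples
        ``neighbors[i]`` is the sorted tuple of area ids adjacent to ``i``.
        Symmetry and absence of self-loops are validated at construction.
    """

    n: int
    neighbors: tuple[tuple[int, ...], ...]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one area")
        if len(self.neighbors) != self.n:
            raise ValueError("neighbor list length does not match n")
        neigh_sets = [set(nb) for nb in self.neighbors]
        for i, nbs in enumerate(self.neighbors):
            for j in nbs:
                if j == i:
                    raise ValueError(f"self-loop at area {i}")
                if not (0 <= j < self.n):
                    raise ValueError(f"area {i} lists unknown neighbor {j}")
                if i not in neigh_sets[j]:
                    raise AsymmetricWeightsError(
                        f"edge ({i}, {j}) present but ({j}, {i}) missing"
                    )

    # -- basic graph views -------------------------------------------------

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Unordered edge set as (min, max) pairs."""
        return {
            (i, j) for i, nbs in enumerate(self.neighbors) for j in nbs if i < j
        }

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors) // 2

    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency matrix (CSR)."""
        if "adj" not in self._cache:
            indptr = np.zeros(self.n + 1, dtype=np.int64)
            indptr[1:] = np.cumsum([len(nb) for nb in self.neighbors])
            indices = np.fromiter(
                (j for nbs in self.neighbors for j in nbs),
                dtype=np.int64,
                count=indptr[-1],
            )
            data = np.ones(indptr[-1], dtype=float)
            self._cache["adj"] = sp.csr_matrix(
                (data, indices, indptr), shape=(self.n, self.n)
            )
        return self._cache["adj"]

    def is_connected(self) -> bool:
        if "connected" not in self._cache:
            ncomp = sp.csgraph.connected_components(
                self.adjacency(), directed=False, return_labels=False
            )
            self._cache["connected"] = ncomp == 1
        return self._cache["connected"]

    # -- row-standardized view --------------------------------------------

    def row_standardized(self) -> sp.csr_matrix:
        """Row-standardized weights: ``w_ij = 1/deg(i)`` for each neighbor j.

        Every row sums to one.  Raises :class:`IsolatedAreaError` naming the
        first isolated area if any area has no neighbors.
        """
        if "wstd" not in self._cache:
            deg = self.degrees
            if np.any(deg == 0):
                isolate = int(np.argmin(deg))
                raise IsolatedAreaError(
                    f"area {isolate} has no neighbors; cannot row-standardize"
                )
            a = self.adjacency().tocsr(copy=True)
            a.data = np.repeat(1.0 / deg, deg)
            self._cache["wstd"] = a
        return self._cache["wstd"]

    def standardized_eigenvalues(self) -> np.ndarray:
        """Real spectrum of the row-standardized weights.

        ``D^{-1} A`` is similar to the symmetric ``D^{-1/2} A D^{-1/2}``, so
        its eigenvalues are real and lie in [-1, 1]; they feed the SAR
        log-determinant.  Cached (O(n^3) dense eigendecomposition).
        """
        if "eigs" not in self._cache:
            deg = self.degrees.astype(float)
            if np.any(deg == 0):
                raise IsolatedAreaError("isolated area: spectrum undefined")
            d = 1.0 / np.sqrt(deg)
            sym = self.adjacency().toarray() * np.outer(d, d)
            self._cache["eigs"] = np.linalg.eigvalsh(sym)
        return self._cache["eigs"]


def row_standardize(w: SpatialWeights) -> sp.csr_matrix:
    """Functional alias for :meth:`SpatialWeights.row_standardized`."""
    return w.row_standardized()


def rook_lattice(nrows: int, ncols: int) -> SpatialWeights:
    """Regular lattice with rook contiguity (cells sharing an edge).

    Area ids are 0-based and row-major: cell ``(r, c)`` has id
    ``r * ncols + c``.  The edge count is ``nrows*(ncols-1) + ncols*(nrows-1)``
    and the mean degree approaches 4 on large lattices — the regime the
    S-maup statistic is calibrated for.
    """
    if nrows < 1 or ncols < 1 or nrows * ncols < 2:
        raise ValueError("lattice must contain at least 2 cells")
    neighbors: list[tuple[int, ...]] = []
    for r in range(nrows):
        for c in range(ncols):
            nbs = []
            if r > 0:
                nbs.append((r - 1) * ncols + c)
            if c > 0:
                nbs.append(r * ncols + c - 1)
            if c < ncols - 1:
                nbs.append(r * ncols + c + 1)
            if r < nrows - 1:
                nbs.append((r + 1) * ncols + c)
            neighbors.append(tuple(sorted(nbs)))
    return SpatialWeights(nrows * ncols, tuple(neighbors))


# -- GAL interchange -------------------------------------------------------


def read_gal(path, strict: bool = True) -> SpatialWeights:
    """Read a GAL weights file.

    Dialect: first line ``n``; then, per area, a line ``id k`` followed by a
    line of ``k`` neighbor ids.  In strict mode (default) an asymmetric
    listing raises :class:`AsymmetricWeightsError`; with ``strict=False`` the
    graph is symmetrized and a warning is emitted.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"empty GAL file: {path}")
    pos = 0

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"truncated GAL file: {path}")
        tok = tokens[pos]
        pos += 1
        return tok

    # some GAL headers carry extra fields; the area count is the first integer
    n = int(take())
    listed: dict[int, list[int]] = {}
    for _ in range(n):
        area = int(take())
        k = int(take())
        listed[area] = [int(take()) for _ in range(k)]
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GAL file: {path}")
    if sorted(listed) != list(range(n)):
        raise ValueError("GAL area ids must be contiguous integers 0..n-1")

    sets = {i: set(nbs) for i, nbs in listed.items()}
    for i, nbs in sets.items():
        for j in nbs:
            if i not in sets.get(j, ()):  # missing reciprocal
                if strict:
                    raise AsymmetricWeightsError(
                        f"GAL lists neighbor pair ({i}, {j}) but not ({j}, {i})"
                    )
                warnings.warn(
                    f"symmetrizing GAL: adding missing edge ({j}, {i})",
                    stacklevel=2,
                )
    if not strict:
        for i in list(sets):
            for j in list(sets[i]):
                sets[j].add(i)
    return SpatialWeights(n, tuple(tuple(sorted(sets[i])) for i in range(n)))


def write_gal(w: SpatialWeights, path) -> None:
    """Write a GAL weights file (read/write round-trips exactly)."""
    lines = [str(w.n)]
    for i, nbs in enumerate(w.neighbors):
        lines.append(f"{i} {len(nbs)}")
        lines.append(" ".join(map(str, nbs)))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
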