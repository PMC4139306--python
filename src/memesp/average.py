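"""Voxel-wise ensemble averages: arithmetic mean, exact median, remedian.

The remedian (Rousseeuw & Bassett) approximates the median of a long stream
with k cascading buffers of b values each (capacity b^k): whenever a buffer
fills, its median is pushed one level up and the buffer is cleared.  It is
the robust average used for membrane potential ensembles where holding all
grids in memory is impractical.  Only one incoming grid plus k*b values per
voxel are resident at any time.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .grid import GridError, GridSpec, PotentialGrid, specs_coincide


class CapacityError(RuntimeError):
    pass


class RemedianAccumulator:
    """Streaming per-voxel remedian state.

    Parameters
    ----------
    base : odd buffer size b (default 9).
    depth : number of cascaded buffers k (default 3); capacity is b**k
        (9**3 = 729 with the defaults).
    """

    def __init__(self, base: int = 9, depth: int = 3) -> None:
        if base < 3 or base % 2 == 0:
            raise ValueError("base must be odd and >= 3")
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.base = base
        self.depth = depth
        self.n = 0
        self._spec: GridSpec | None = None
        self._buffers: np.ndarray | None = None   # (depth, base, *dims)
        self._fill = np.zeros(depth, dtype=int)

    @property
    def capacity(self) -> int:
        return self.base ** self.depth

    @property
    def grid_spec(self) -> GridSpec | None:
        return self._spec

    def update(self, grid: PotentialGrid) -> "RemedianAccumulator":
        """Feed one grid into the accumulator (streaming)."""
        if self.n >= self.capacity:
            raise CapacityError(
                f"remedian capacity {self.capacity} exceeded; "
                f"use a larger base or depth"
            )
        if self._spec is None:
            self._spec = grid.spec
            self._buffers = np.empty((self.depth, self.base) + tuple(grid.dims))
        elif not specs_coincide(self._spec, grid.spec):
            raise GridError("grid does not coincide with the accumulator's grid spec")
        self._insert(0, np.asarray(grid.values, dtype=float))
        self.n += 1
        return self

    def _insert(self, level: int, values: np.ndarray) -> None:
        self._buffers[level, self._fill[level]] = values
        self._fill[level] += 1
        if self._fill[level] == self.base and level < self.depth - 1:
            med = np.median(self._buffers[level], axis=0)
            self._fill[level] = 0
            self._insert(level + 1, med)

    def finalize(self) -> PotentialGrid:
        """Complete the remedian over whatever has been streamed so far.

        At partial fill the result is the weighted median of all resident
        buffer entries, a level-i entry carrying weight b**i (each stands in
        for b**i original values).  At full capacity this reduces to the
        plain median of the top-level buffer.
        """
        if self.n == 0:
            raise GridError("cannot finalize an empty accumulator")
        vals, weights = [], []
        for level in range(self.depth):
            c = self._fill[level]
            if c:
                vals.append(self._buffers[level, :c])
                weights.extend([self.base ** level] * c)
        stacked = np.concatenate(vals, axis=0)
        result = weighted_median(stacked, np.asarray(weights, dtype=np.int64))
        return PotentialGrid(
            spec=self._spec, values=result,
            label=f"remedian (b={self.base}, k={self.depth}, n={self.n})",
            metadata={"n": self.n, "base": self.base, "depth": self.depth},
        )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted median along axis 0 (midpoint rule at exact half-weight ties).

    ``values`` has shape (m, ...), ``weights`` shape (m,) with positive
    integer weights.
    """
    m = values.shape[0]
    if m == 1:
        return values[0].copy()
    order = np.argsort(values, axis=0, kind="stable")
    v_sorted = np.take_along_axis(values, order, axis=0)
    w = np.broadcast_to(weights.reshape((m,) + (1,) * (values.ndim - 1)), values.shape)
    w_sorted = np.take_along_axis(w, order, axis=0)
    cs2 = 2 * np.cumsum(w_sorted, axis=0)
    total = int(weights.sum())
    ge = cs2 >= total
    j = ge.argmax(axis=0)
    j_idx = j[None, ...]
    vj = np.take_along_axis(v_sorted, j_idx, axis=0)[0]
    tie = np.take_along_axis(cs2, j_idx, axis=0)[0] == total
    j1 = np.minimum(j + 1, m - 1)[None, ...]
    vj1 = np.take_along_axis(v_sorted, j1, axis=0)[0]
    return np.where(tie, 0.5 * (vj + vj1), vj)


def remedian_grid(grids: Iterable[PotentialGrid], base: int = 9, depth: int = 3) -> PotentialGrid:
    """One-shot remedian over a stream of grids."""
    acc = RemedianAccumulator(base=base, depth=depth)
    for g in grids:
        acc.update(g)
    return acc.finalize()


def mean_grid(grids: Iterable[PotentialGrid]) -> PotentialGrid:
    """Single-pass, numerically stable (incremental) voxel-wise mean."""
    mean = None
    spec = None
    count = 0
    for g in grids:
        count += 1
        if mean is None:
            spec = g.spec
            mean = np.asarray(g.values, dtype=float).copy()
        else:
            if not specs_coincide(spec, g.spec):
                raise GridError(f"grid #{count} does not coincide with the first grid")
            mean += (np.asarray(g.values, dtype=float) - mean) / count
    if mean is None:
        raise GridError("cannot average an empty stream")
    return PotentialGrid(spec=spec, values=mean, label=f"mean (n={count})",
                         metadata={"n": count})


def exact_median_grid(grids: Sequence[PotentialGrid]) -> PotentialGrid:
    """Exact voxel-wise median (test-scale; holds all grids in memory)."""
    grids = list(grids)
    if not grids:
        raise GridError("cannot take the median of an empty list")
    spec = grids[0].spec
    for i, g in enumerate(grids[1:], start=1):
        if not specs_coincide(spec, g.spec):
            raise GridError(f"grid #{i} does not coincide with the first grid")
    stacked = np.stack([np.asarray(g.values, dtype=float) for g in grids], axis=0)
    med = np.median(stacked, axis=0)
    return PotentialGrid(spec=spec, values=med, label=f"median (n={len(grids)})",
                         metadata={"n": len(grids)})
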