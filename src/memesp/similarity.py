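"""Skin-region Hodgkin similarity, electrostatic distances and their
ensemble statistics (PIPSA-style comparison of potential grids).

Two potentials are compared over a "skin": the shell of solvent-side voxels
lying between the molecular surface inflated by a probe radius and the same
surface inflated by probe + skin thickness, restricted to a sphere around a
reference atom (the probe-lipid P1 phosphate by default).  The Hodgkin
similarity index

    SI(a, b) = 2 sum(a_i b_i) / (sum(a_i^2) + sum(b_i^2))

lies in [-1, 1]; the electrostatic distance D = sqrt(2 - 2 SI) ranges from 0
(identical potentials) to 2 (anticorrelated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import GridError, GridSpec, PotentialGrid, specs_coincide
from .structure import StructureModel


@dataclass
class SkinMaskSpec:
    """Skin geometry: probe 2 Å, skin 3 Å, sphere 10 or 14 Å around P1."""

    probe_radius: float = 2.0
    skin_thickness: float = 3.0
    sphere_radius: float = 14.0
    center: str | tuple = "P1"   # role tag or explicit (x, y, z)

    def __post_init__(self) -> None:
        if self.probe_radius <= 0 or self.skin_thickness <= 0 or self.sphere_radius <= 0:
            raise ValueError("all skin radii must be > 0")


@dataclass
class SkinMask:
    grid_spec: GridSpec
    values: np.ndarray           # bool, shape = dims
    spec: SkinMaskSpec | None = None

    @property
    def size(self) -> int:
        return int(np.count_nonzero(self.values))

    def __and__(self, other: "SkinMask") -> "SkinMask":
        if not specs_coincide(self.grid_spec, other.grid_spec):
            raise GridError("cannot intersect masks on non-coincident grids")
        return SkinMask(self.grid_spec, self.values & other.values, self.spec)


def _inflate_union(structure: StructureModel, grid_spec: GridSpec, inflation: float) -> np.ndarray:
    """Boolean voxel map: center within (atom radius + inflation) of any atom."""
    out = np.zeros(grid_spec.dims, dtype=bool)
    dims = np.asarray(grid_spec.dims)
    for pos, radius in zip(structure.coords, structure.radii):
        r = radius + inflation
        lo = np.maximum(np.floor(grid_spec.point_to_index(pos - r)).astype(int), 0)
        hi = np.minimum(np.ceil(grid_spec.point_to_index(pos + r)).astype(int) + 1, dims)
        if np.any(lo >= hi):
            continue
        ax = [grid_spec.axis_coords(d)[lo[d]:hi[d]] - pos[d] for d in range(3)]
        d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return out


def skin_mask(structure: StructureModel, grid_spec: GridSpec,
              spec: SkinMaskSpec | None = None) -> SkinMask:
    """Build the skin-region voxel selection for a structure on a grid.

    A voxel is selected iff it lies outside every vdW sphere inflated by the
    probe radius, inside some sphere inflated by probe + skin, and within
    the comparison sphere around the center.
    """
    spec = spec or SkinMaskSpec()
    if len(structure) == 0:
        raise GridError("cannot build a skin for an empty structure")
    if isinstance(spec.center, str):
        center = structure.role_position(spec.center)
    else:
        center = np.asarray(spec.center, dtype=float)
    inner = _inflate_union(structure, grid_spec, spec.probe_radius)
    outer = _inflate_union(structure, grid_spec, spec.probe_radius + spec.skin_thickness)
    x, y, z = grid_spec.meshgrid()
    within = (
        (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        <= spec.sphere_radius ** 2
    )
    return SkinMask(grid_spec, outer & ~inner & within, spec)


def hodgkin_index(a: PotentialGrid, b: PotentialGrid, mask: SkinMask) -> float:
    """Hodgkin similarity index of two coincident grids over a skin mask."""
    if not (specs_coincide(a.spec, mask.grid_spec) and specs_coincide(b.spec, mask.grid_spec)):
        raise GridError("grids and mask must share one grid spec")
    sel = mask.values
    if not sel.any():
        raise GridError("empty skin mask")
    va = np.asarray(a.values, dtype=float)[sel]
    vb = np.asarray(b.values, dtype=float)[sel]
    denom = float(va @ va + vb @ vb)
    if denom == 0.0:
        raise GridError("Hodgkin index undefined: both potentials vanish on the mask")
    return float(2.0 * (va @ vb) / denom)


def electrostatic_distance(si: float) -> float:
    """D = sqrt(2 - 2 SI); 0 for identical, sqrt(2) for orthogonal, 2 for
    anticorrelated potentials."""
    if not -1.0 - 1e-9 <= si <= 1.0 + 1e-9:
        raise ValueError(f"similarity index {si} outside [-1, 1]")
    return math.sqrt(max(2.0 - 2.0 * si, 0.0))


@dataclass
class DistanceMatrix:
    """Symmetric all-vs-all electrostatic distance matrix in [0, 2]."""

    values: np.ndarray
    labels: list = field(default_factory=list)
    timestamps: list | None = None      # ns

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-9 or v.max() > 2.0 + 1e-9:
            raise ValueError("distances must lie in [0, 2]")
        self.values = v
        if not self.labels:
            self.labels = [f"grid{i:04d}" for i in range(len(v))]

    def __len__(self) -> int:
        return len(self.values)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.values), k=1)
        return self.values[iu]

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.6f"
        )


def pairwise_matrix(grids: Sequence[PotentialGrid],
                    mask: SkinMask | None = None,
                    masks: Sequence[SkinMask] | None = None,
                    labels: Sequence[str] | None = None,
                    timestamps: Sequence[float] | None = None) -> DistanceMatrix:
    """All-vs-all electrostatic distances.

    Either a single shared ``mask`` (built from a designated reference
    structure; the default policy) or per-grid ``masks`` (per-pair
    intersection policy) must be given.
    """
    grids = list(grids)
    if len(grids) < 2:
        raise GridError("need at least two grids")
    if (mask is None) == (masks is None):
        raise ValueError("provide exactly one of mask= or masks=")
    n = len(grids)
    d = np.zeros((n, n))
    if mask is not None:
        sel = mask.values
        if not sel.any():
            raise GridError("empty skin mask")
        vecs = [np.asarray(g.values, dtype=float)[sel] for g in grids]
        sq = [float(v @ v) for v in vecs]
        for i in range(n):
            for j in range(i + 1, n):
                denom = sq[i] + sq[j]
                if denom == 0.0:
                    raise GridError("Hodgkin index undefined: both potentials vanish on the mask")
                si = 2.0 * float(vecs[i] @ vecs[j]) / denom
                d[i, j] = d[j, i] = electrostatic_distance(min(max(si, -1.0), 1.0))
    else:
        if len(masks) != n:
            raise ValueError("need one mask per grid")
        for i in range(n):
            for j in range(i + 1, n):
                si = hodgkin_index(grids[i], grids[j], masks[i] & masks[j])
                d[i, j] = d[j, i] = electrostatic_distance(min(max(si, -1.0), 1.0))
    labels = list(labels) if labels is not None else [g.label or f"grid{i:04d}" for i, g in enumerate(grids)]
    return DistanceMatrix(values=d, labels=labels,
                          timestamps=list(timestamps) if timestamps is not None else None)


def distance_stats(m: DistanceMatrix, bins: int = 20) -> dict:
    """Mean, sample SD and histogram of the strict upper triangle."""
    if len(m) < 2:
        raise ValueError("need at least a 2x2 matrix")
    tri = m.upper_triangle()
    hist, edges = np.histogram(tri, bins=bins, range=(0.0, 2.0))
    return {
        "mean": float(tri.mean()),
        "sd": float(tri.std(ddof=1)) if tri.size > 1 else 0.0,
        "histogram": (hist, edges),
        "n_pairs": int(tri.size),
    }


def distance_autocorrelation(m: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Lag autocorrelation of the electrostatic distance.

    For uniformly spaced snapshots, ACF(tau) = 1 - <D(t, t+tau)>_t / <D>,
    where <D> is the mean over all distinct pairs: 1 at lag 0 (D(t,t) = 0),
    ~0 for an ensemble without time correlation, negative when snapshots a
    lag apart are *less* similar than average.  Returns (lags, acf) with
    lags in the matrix's time units (index units if timestamps are absent).
    """
    n = len(m)
    if n < 3:
        raise ValueError("need at least three snapshots")
    if m.timestamps is not None:
        t = np.asarray(m.timestamps, dtype=float)
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("timestamps must be uniformly spaced")
        dt = float(steps[0])
    else:
        dt = 1.0
    overall = float(m.upper_triangle().mean())
    if overall == 0.0:
        raise ValueError("autocorrelation undefined: all distances are zero")
    lags = np.arange(n)
    acf = np.empty(n)
    for tau in range(n):
        diag = np.diagonal(m.values, offset=tau)
        acf[tau] = 1.0 - float(diag.mean()) / overall
    return lags * dt, acf


def cluster_order(m: DistanceMatrix):
    """Leaf ordering from average-linkage hierarchical clustering on D
    (heatmap presentation order; does not change any distance)."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    link = hierarchy.linkage(squareform(m.values, checks=False), method="average")
    return hierarchy.leaves_list(link)
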