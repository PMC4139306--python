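"""Isopotential bulge height above the probe-lipid phosphate.

The headline geometric statistic: the largest z at which the potential
column above the P1 phosphate still reaches the -0.6 kcal/mol/e (1 kT/e at
296 K) contour, reported relative to either the P1 position or the mean
plane of the surrounding POPC phosphates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import GeometrySpec, popc_reference_z
from .grid import GridError, PotentialGrid
from .structure import StructureModel


@dataclass
class BulgeSpec:
    """Threshold and search geometry for the bulge measurement."""

    threshold: float = -0.6            # kcal/mol/e
    reference: str = "P1"              # or "popc_plane"
    surface_offset: float = 0.05       # Å above P1 where the scan starts
    lateral_search_radius: float = 0.0  # Å; 0 = the vertical line through P1

    def __post_init__(self) -> None:
        if self.threshold >= 0:
            raise ValueError("threshold must be negative for this system")
        if self.surface_offset < 0 or self.lateral_search_radius < 0:
            raise ValueError("offsets/radii must be >= 0")


def _column_profile(grid: PotentialGrid, x: float, y: float) -> np.ndarray:
    """Potential along the vertical line (x, y, z_k), bilinear in xy."""
    nz = grid.dims[2]
    fx = (x - grid.origin[0]) / grid.spacing
    fy = (y - grid.origin[1]) / grid.spacing
    coords = np.vstack([
        np.full(nz, fx), np.full(nz, fy), np.arange(nz, dtype=float),
    ])
    return map_coordinates(np.asarray(grid.values, dtype=float), coords,
                           order=1, mode="nearest")


def _topmost_crossing(zs: np.ndarray, phi: np.ndarray, threshold: float,
                      z_start: float) -> float | None:
    """Largest z >= z_start where phi <= threshold, linearly interpolated to
    the crossing with the voxel above."""
    valid = zs >= z_start
    if not valid.any():
        return None
    below = valid & (phi <= threshold)
    if not below.any():
        return None
    k = int(np.max(np.nonzero(below)[0]))
    if k == len(zs) - 1:
        return float(zs[k])  # contour leaves the grid top
    z0, z1 = zs[k], zs[k + 1]
    p0, p1 = phi[k], phi[k + 1]
    if p1 == p0:
        return float(z0)
    return float(z0 + (threshold - p0) / (p1 - p0) * (z1 - z0))


def bulge_height(grid: PotentialGrid, p1: Sequence[float],
                 spec: BulgeSpec | None = None,
                 reference_z: float | None = None) -> float | None:
    """Height of the threshold isopotential above P1 (Å), or None.

    Scans voxel columns within ``lateral_search_radius`` of the vertical
    line through ``p1``, upward (+z) starting ``surface_offset`` above P1;
    the topmost threshold crossing is located by linear interpolation and
    reported relative to ``reference_z`` (default: z of P1).  Returns None
    when the potential never reaches the threshold above P1.
    """
    spec = spec or BulgeSpec()
    p1 = np.asarray(p1, dtype=float)
    if not grid.spec.contains_point(p1):
        raise GridError(f"P1 position {tuple(p1)} lies outside the grid")
    zs = grid.spec.axis_coords(2)
    z_start = p1[2] + spec.surface_offset
    ref = p1[2] if reference_z is None else float(reference_z)

    candidates: list[tuple[float, float]] = [(p1[0], p1[1])]
    if spec.lateral_search_radius > 0:
        xs, ys = grid.spec.axis_coords(0), grid.spec.axis_coords(1)
        r2 = spec.lateral_search_radius ** 2
        for x in xs[np.abs(xs - p1[0]) <= spec.lateral_search_radius]:
            for y in ys[np.abs(ys - p1[1]) <= spec.lateral_search_radius]:
                if (x - p1[0]) ** 2 + (y - p1[1]) ** 2 <= r2:
                    candidates.append((float(x), float(y)))

    best: float | None = None
    for x, y in candidates:
        z_cross = _topmost_crossing(zs, _column_profile(grid, x, y), spec.threshold, z_start)
        if z_cross is not None and (best is None or z_cross > best):
            best = z_cross
    return None if best is None else best - ref


def bulge_height_popc_ref(grid: PotentialGrid, structure: StructureModel,
                          spec: BulgeSpec | None = None,
                          geometry_spec: GeometrySpec | None = None) -> float | None:
    """Bulge height relative to the mean z of same-leaflet POPC phosphates
    beyond the lateral exclusion radius (15 Å by default)."""
    spec = spec or BulgeSpec(reference="popc_plane")
    p1 = structure.role_position("P1")
    ref_z = popc_reference_z(structure, geometry_spec)
    return bulge_height(grid, p1, spec, reference_z=ref_z)


def ensemble_bulge_heights(grids, structures: Sequence[StructureModel],
                           spec: BulgeSpec | None = None,
                           geometry_spec: GeometrySpec | None = None) -> np.ndarray:
    """Bulge height per snapshot (NaN where no bulge exists)."""
    spec = spec or BulgeSpec()
    out = []
    for grid, structure in zip(grids, structures):
        if spec.reference == "popc_plane":
            h = bulge_height_popc_ref(grid, structure, spec, geometry_spec)
        else:
            h = bulge_height(grid, structure.role_position("P1"), spec)
        out.append(np.nan if h is None else h)
    return np.asarray(out)


def surface_shell_values(grid: PotentialGrid, structure: StructureModel,
                         offset: float = 0.05, points_per_atom: int = 64,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Sample the potential on a shell ``offset`` Å outside the vdW surface.

    Points are spread on each atom's sphere of radius (r + offset) by a
    Fibonacci lattice and kept only where they are outside every other
    atom's offset sphere (i.e. on the union surface).  Returns (points,
    values) with trilinear interpolation of the grid at the points.
    """
    i = np.arange(points_per_atom, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zdir = 1.0 - 2.0 * (i + 0.5) / points_per_atom
    rho = np.sqrt(np.maximum(1.0 - zdir ** 2, 0.0))
    unit = np.column_stack([rho * np.cos(golden * i), rho * np.sin(golden * i), zdir])

    pts = []
    for ai, (pos, radius) in enumerate(zip(structure.coords, structure.radii)):
        cand = pos + (radius + offset) * unit
        keep = np.ones(len(cand), dtype=bool)
        for bi, (opos, oradius) in enumerate(zip(structure.coords, structure.radii)):
            if bi == ai:
                continue
            d2 = np.sum((cand - opos) ** 2, axis=1)
            keep &= d2 >= (oradius + offset) ** 2 * (1.0 - 1e-12)
        pts.append(cand[keep])
    points = np.concatenate(pts, axis=0) if pts else np.zeros((0, 3))
    inside = np.all((points >= np.asarray(grid.origin)) &
                    (points <= np.asarray(grid.spec.upper_corner)), axis=1)
    points = points[inside]
    return points, grid.interpolate(points)
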