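"""Uniform 3-D scalar potential grids and ensemble coincidence checks."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Header tolerance (Angstrom) used when deciding whether grids coincide.
COINCIDENCE_TOL = 1e-6


class GridError(ValueError):
    """Invalid grid construction or incompatible grid combination."""


@dataclass
class GridSpec:
    """Geometry of a uniform grid: dims, spacing (Å) and origin (Å).

    The origin is the Cartesian position of the *center* of voxel (0, 0, 0);
    indices are 0-based and voxel centers sit at ``origin + index * spacing``.
    """

    dims: tuple[int, int, int]
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)  # type: ignore[assignment]
        if len(self.dims) != 3 or any(d < 2 for d in self.dims):
            raise GridError(f"dims must be three integers >= 2, got {self.dims}")
        self.spacing = float(self.spacing)
        if not self.spacing > 0:
            raise GridError(f"spacing must be > 0, got {self.spacing}")
        self.origin = tuple(float(x) for x in self.origin)  # type: ignore[assignment]

    @classmethod
    def centered(cls, center: Sequence[float], dims: Sequence[int], spacing: float) -> "GridSpec":
        """Grid spec whose geometric center is ``center``."""
        dims = tuple(int(d) for d in dims)
        origin = tuple(float(c) - (d - 1) * spacing / 2.0 for c, d in zip(center, dims))
        return cls(dims=dims, spacing=float(spacing), origin=origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis."""
        return self.origin[axis] + self.spacing * np.arange(self.dims[axis])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2), indexing="ij"
        )

    @property
    def upper_corner(self) -> tuple[float, float, float]:
        return tuple(
            o + (d - 1) * self.spacing for o, d in zip(self.origin, self.dims)
        )

    def contains_point(self, point: Sequence[float]) -> bool:
        return all(
            o - 1e-9 <= p <= u + 1e-9
            for p, o, u in zip(point, self.origin, self.upper_corner)
        )

    def point_to_index(self, point: Sequence[float]) -> np.ndarray:
        """Fractional (float) voxel index of a Cartesian point."""
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / self.spacing


@dataclass
class PotentialGrid:
    """A scalar potential field (kcal/mol/e) on a uniform grid.

    ``values`` has shape ``dims`` and is indexed [ix, iy, iz].
    """

    spec: GridSpec
    values: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.spec.dims):
            raise GridError(
                f"values shape {self.values.shape} != dims {self.spec.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise GridError(
                f"non-finite potential value at voxel {tuple(int(i) for i in bad)}"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.spec.dims

    @property
    def spacing(self) -> float:
        return self.spec.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.spec.origin

    def copy(self, **changes) -> "PotentialGrid":
        out = replace(self, values=self.values.copy(), metadata=dict(self.metadata))
        for k, v in changes.items():
            setattr(out, k, v)
        return out

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the potential at Cartesian points (n, 3)."""
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - np.asarray(self.spec.origin)) / self.spec.spacing
        return map_coordinates(self.values.astype(float), idx.T, order=1, mode="nearest")


def specs_coincide(a: GridSpec, b: GridSpec, tol: float = COINCIDENCE_TOL) -> bool:
    return (
        a.dims == b.dims
        and abs(a.spacing - b.spacing) <= tol
        and all(abs(x - y) <= tol for x, y in zip(a.origin, b.origin))
    )


def assert_coincident(grids: Iterable[PotentialGrid], tol: float = COINCIDENCE_TOL) -> list[PotentialGrid]:
    """Validate that all grids share dims/spacing/origin within ``tol``.

    Returns the grids as a list usable by the averaging operations; raises
    :class:`GridError` naming the first offending grid and field otherwise.
    """
    grids = list(grids)
    if len(grids) < 2:
        raise GridError("need at least two grids to check coincidence")
    ref = grids[0].spec
    for i, g in enumerate(grids[1:], start=1):
        name = g.label or f"grid #{i}"
        if g.spec.dims != ref.dims:
            raise GridError(f"{name}: dims {g.spec.dims} != {ref.dims}")
        if abs(g.spec.spacing - ref.spacing) > tol:
            raise GridError(f"{name}: spacing {g.spec.spacing} != {ref.spacing}")
        for ax, (x, y) in enumerate(zip(g.spec.origin, ref.origin)):
            if abs(x - y) > tol:
                raise GridError(f"{name}: origin[{ax}] {x} != {y}")
    return grids
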