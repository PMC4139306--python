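"""Finite-difference linearized Poisson-Boltzmann solver with two-grid
focusing.

The potential phi (kcal/mol/e) of a charge distribution in a two-dielectric
medium with mobile 1:1 electrolyte satisfies

    div(eps grad phi) - kbar^2 phi = -4 pi C rho

with C the Coulomb constant in kcal*Å/(mol*e^2) and kbar^2 = eps_solvent *
kappa^2 outside the ion-accessible boundary, zero inside.  Discretization is
the standard 7-point variable-coefficient stencil on voxel centers with
harmonic-mean face dielectrics and trilinear charge spreading, solved by
red-black successive over-relaxation.  The result is deterministic at
convergence, independent of sweep order.

Focusing solves a coarse outer grid with analytic Debye-Hueckel boundary
values, then a fine inner grid whose Dirichlet boundary is interpolated
trilinearly from the outer solution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_KCAL, KB_KCAL, debye_kappa
from .grid import GridSpec, PotentialGrid
from .structure import StructureModel

FOUR_PI_C = 4.0 * math.pi * COULOMB_KCAL


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PBConfig:
    """Solver settings; defaults follow the bilayer focusing protocol
    (outer 271x271x222 at 2 Å, inner 201^3 at 0.5 Å centered on P1,
    eps_in 2 / eps_out 80, 100 mM, 2 Å ion exclusion, 296 K)."""

    solute_dielectric: float = 2.0
    solvent_dielectric: float = 80.0
    ionic_strength: float = 0.1          # mol/L
    ion_exclusion_radius: float = 2.0    # Å
    temperature: float = 296.0           # K
    outer_dims: tuple[int, int, int] = (271, 271, 222)
    outer_spacing: float = 2.0
    inner_dims: tuple[int, int, int] = (201, 201, 201)
    inner_spacing: float = 0.5
    tolerance: float = 1e-6              # relative residual
    max_iterations: int = 20000
    nonlinear: bool = False
    omega: float | None = None           # SOR factor; None = auto

    def __post_init__(self) -> None:
        if self.solute_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectrics must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.solvent_dielectric, self.temperature)

    @property
    def thermal_potential(self) -> float:
        """kT/e in kcal/mol/e."""
        return KB_KCAL * self.temperature


@dataclass
class MediaMaps:
    """Voxelized media for one grid spec: voxel dielectric labels, modified
    screening kbar^2 (Å^-2, zero in the ion-excluded region) and trilinearly
    spread source charge (e per voxel)."""

    grid_spec: GridSpec
    dielectric: np.ndarray
    kappa2: np.ndarray
    charge: np.ndarray
    structure: StructureModel | None = None

    def __post_init__(self) -> None:
        if np.any(self.kappa2 < 0):
            raise ValueError("kbar^2 must be >= 0")


def _sphere_mask_apply(arr: np.ndarray, spec: GridSpec, center, radius: float, value) -> None:
    """Set arr voxels whose centers lie within ``radius`` of ``center``."""
    lo = np.maximum(np.floor(spec.point_to_index(np.asarray(center) - radius)).astype(int), 0)
    hi = np.minimum(
        np.ceil(spec.point_to_index(np.asarray(center) + radius)).astype(int) + 1,
        np.asarray(spec.dims),
    )
    if np.any(lo >= hi):
        return
    ax = [spec.axis_coords(d)[lo[d]:hi[d]] - center[d] for d in range(3)]
    d2 = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    sub = arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[d2 <= radius * radius] = value


def build_media_maps(structure: StructureModel, grid_spec: GridSpec,
                     config: PBConfig) -> MediaMaps:
    """Rasterize dielectric, screening and charge maps for one grid.

    The dielectric boundary is the van der Waals surface: voxel centers
    inside any atom sphere get the solute dielectric.  kbar^2 is zeroed
    inside the vdW surface inflated by the ion exclusion radius.  Charges
    are spread with trilinear weights onto their 8 neighboring voxels
    (charge-conserving); atoms outside the grid are clipped with a warning.
    """
    dims = grid_spec.dims
    eps = np.full(dims, config.solvent_dielectric)
    k2 = np.full(dims, config.solvent_dielectric * config.kappa ** 2)
    q = np.zeros(dims)

    for pos, radius in zip(structure.coords, structure.radii):
        if radius <= 0:
            raise ValueError(f"zero-radius atom at {tuple(pos)}")
        _sphere_mask_apply(eps, grid_spec, pos, radius, config.solute_dielectric)
        _sphere_mask_apply(k2, grid_spec, pos, radius + config.ion_exclusion_radius, 0.0)

    clipped = False
    for pos, charge in zip(structure.coords, structure.charges):
        if charge == 0.0:
            continue
        f = grid_spec.point_to_index(pos)
        if np.any(f < 0) or np.any(f > np.asarray(dims) - 1):
            clipped = True
            f = np.clip(f, 0, np.asarray(dims) - 1)
        i0 = np.minimum(np.floor(f).astype(int), np.asarray(dims) - 2)
        t = f - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (t[0] if dx else 1 - t[0])
                        * (t[1] if dy else 1 - t[1])
                        * (t[2] if dz else 1 - t[2])
                    )
                    q[i0[0] + dx, i0[1] + dy, i0[2] + dz] += charge * w
    if clipped:
        warnings.warn("atom(s) outside the grid: charge spreading clipped to the box")
    return MediaMaps(grid_spec=grid_spec, dielectric=eps, kappa2=k2, charge=q,
                     structure=structure)


def dh_potential_at(structure: StructureModel, points: np.ndarray,
                    config: PBConfig) -> np.ndarray:
    """Debye-Hueckel superposition at Cartesian points (boundary values).

    Per source atom the ion distance of closest approach is the atom radius
    plus the ion exclusion radius.
    """
    kappa = config.kappa
    pts = np.atleast_2d(points)
    phi = np.zeros(len(pts))
    for pos, charge, radius in zip(structure.coords, structure.charges, structure.radii):
        if charge == 0.0:
            continue
        r = np.linalg.norm(pts - pos, axis=1)
        r = np.maximum(r, 1e-3)
        a = radius + config.ion_exclusion_radius
        phi += (
            COULOMB_KCAL * charge / (config.solvent_dielectric * (1.0 + kappa * a))
            * np.exp(-kappa * (r - a)) / r
        )
    return phi


def _boundary_points(spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Indices (n,3) and coordinates (n,3) of all boundary voxels."""
    nx, ny, nz = spec.dims
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    mask = (
        (ii == 0) | (ii == nx - 1) | (jj == 0) | (jj == ny - 1)
        | (kk == 0) | (kk == nz - 1)
    )
    idx = np.column_stack([ii[mask], jj[mask], kk[mask]])
    coords = np.asarray(spec.origin) + idx * spec.spacing
    return idx, coords


def solve(maps: MediaMaps, config: PBConfig,
          boundary: np.ndarray | str = "dh_analytic") -> PotentialGrid:
    """Solve the (linearized) PB equation on the maps' grid.

    ``boundary`` is either a full-shape array whose face values are used as
    Dirichlet conditions, or ``"dh_analytic"`` to use the screened-Coulomb
    superposition of the structure's charges, or ``"zero"``.
    """
    spec = maps.grid_spec
    h = spec.spacing
    nx, ny, nz = spec.dims
    phi = np.zeros(spec.dims)
    if isinstance(boundary, np.ndarray):
        if boundary.shape != tuple(spec.dims):
            raise ValueError("boundary array must have the grid's shape")
        phi[:] = boundary
        phi[1:-1, 1:-1, 1:-1] = 0.0
    elif boundary == "dh_analytic":
        if maps.structure is None:
            raise ValueError("analytic boundary requires maps built from a structure")
        idx, coords = _boundary_points(spec)
        phi[idx[:, 0], idx[:, 1], idx[:, 2]] = dh_potential_at(maps.structure, coords, config)
    elif boundary != "zero":
        raise ValueError(f"unknown boundary {boundary!r}")

    phi, iterations = _sor(phi, maps, config)
    label = "PB potential (nonlinear)" if config.nonlinear else "PB potential (linear)"
    return PotentialGrid(spec=spec, values=phi, label=label,
                         metadata={"solver": "red-black SOR", "tolerance": config.tolerance,
                                   "iterations": iterations})


def _face_eps(eps: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hx = 2.0 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:])
    hy = 2.0 * eps[:, :-1] * eps[:, 1:] / (eps[:, :-1] + eps[:, 1:])
    hz = 2.0 * eps[:, :, :-1] * eps[:, :, 1:] / (eps[:, :, :-1] + eps[:, :, 1:])
    return hx, hy, hz


def _sor(phi: np.ndarray, maps: MediaMaps, config: PBConfig,
         extra_source: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Red-black SOR on the interior; Dirichlet faces held fixed in phi."""
    h = maps.grid_spec.spacing
    ex, ey, ez = _face_eps(maps.dielectric)
    eW, eE = ex[:-1, 1:-1, 1:-1], ex[1:, 1:-1, 1:-1]
    eS, eN = ey[1:-1, :-1, 1:-1], ey[1:-1, 1:, 1:-1]
    eD, eU = ez[1:-1, 1:-1, :-1], ez[1:-1, 1:-1, 1:]
    k2 = maps.kappa2[1:-1, 1:-1, 1:-1]
    den = h * (eW + eE + eS + eN + eD + eU) + h ** 3 * k2
    b = FOUR_PI_C * maps.charge[1:-1, 1:-1, 1:-1]
    if extra_source is not None:
        b = b + extra_source

    if config.nonlinear and extra_source is None:
        return _nonlinear_outer(phi, maps, config)

    shape = den.shape
    ii, jj, kk = np.indices(shape)
    red = (ii + jj + kk) % 2 == 0
    black = ~red
    n = max(maps.grid_spec.dims)
    omega = config.omega if config.omega is not None else 2.0 / (1.0 + math.sin(math.pi / n))
    bnorm = np.linalg.norm(b)
    inner = (slice(1, -1),) * 3

    def neighbor_sum() -> np.ndarray:
        return (
            eW * phi[:-2, 1:-1, 1:-1] + eE * phi[2:, 1:-1, 1:-1]
            + eS * phi[1:-1, :-2, 1:-1] + eN * phi[1:-1, 2:, 1:-1]
            + eD * phi[1:-1, 1:-1, :-2] + eU * phi[1:-1, 1:-1, 2:]
        )

    last_rel = math.inf
    for it in range(config.max_iterations):
        for color in (red, black):
            num = h * neighbor_sum() + b
            target = num / den
            cur = phi[inner]
            cur[color] = (1.0 - omega) * cur[color] + omega * target[color]
            phi[inner] = cur
        resid = h * neighbor_sum() + b - den * phi[inner]
        scale = max(bnorm, float(np.linalg.norm(den * phi[inner])), 1e-300)
        last_rel = float(np.linalg.norm(resid)) / scale
        if last_rel <= config.tolerance:
            return phi, it + 1
    raise ConvergenceError(
        f"SOR did not converge: relative residual {last_rel:.3e} after "
        f"{config.max_iterations} iterations"
    )


def _nonlinear_outer(phi: np.ndarray, maps: MediaMaps, config: PBConfig,
                     damping: float = 0.6, outer_tol_factor: float = 10.0,
                     max_outer: int = 60) -> tuple[np.ndarray, int]:
    """Damped fixed-point iteration on the sinh term.

    Each outer pass solves the linear problem with the nonlinear excess
    kbar^2 (phi_T sinh(phi/phi_T) - phi) moved to the source side.
    """
    h = maps.grid_spec.spacing
    phi_t = config.thermal_potential
    k2 = maps.kappa2[1:-1, 1:-1, 1:-1]
    lin_cfg = PBConfig(**{**config.__dict__, "nonlinear": False})
    prev = None
    total_iters = 0
    for _ in range(max_outer):
        inner_phi = phi[1:-1, 1:-1, 1:-1]
        arg = np.clip(inner_phi / phi_t, -30, 30)
        excess = -(h ** 3) * k2 * (phi_t * np.sinh(arg) - inner_phi)
        new, its = _sor(phi.copy(), maps, lin_cfg, extra_source=excess)
        total_iters += its
        phi = phi + damping * (new - phi) if prev is not None else new
        step = float(np.max(np.abs(phi - prev))) if prev is not None else math.inf
        prev = phi.copy()
        if step <= outer_tol_factor * config.tolerance * max(1.0, float(np.max(np.abs(phi)))):
            return phi, total_iters
    raise ConvergenceError("nonlinear fixed-point iteration did not converge")


def focus_solve(structure: StructureModel, config: PBConfig,
                outer_center=None) -> PotentialGrid:
    """Two-grid focusing: coarse outer solve with analytic boundary, then a
    fine inner grid centered on the structure's P1 atom with boundary values
    trilinearly interpolated from the outer solution."""
    from scipy.ndimage import map_coordinates

    p1 = structure.role_position("P1")
    if outer_center is None:
        outer_center = p1
    outer_spec = GridSpec.centered(outer_center, config.outer_dims, config.outer_spacing)
    inner_spec = GridSpec.centered(p1, config.inner_dims, config.inner_spacing)
    for lo_i, hi_i, lo_o, hi_o in zip(inner_spec.origin, inner_spec.upper_corner,
                                      outer_spec.origin, outer_spec.upper_corner):
        if lo_i < lo_o - 1e-9 or hi_i > hi_o + 1e-9:
            raise ValueError("inner grid is not contained in the outer grid")

    outer_maps = build_media_maps(structure, outer_spec, config)
    outer = solve(outer_maps, config, boundary="dh_analytic")

    idx, coords = _boundary_points(inner_spec)
    frac = (coords - np.asarray(outer_spec.origin)) / outer_spec.spacing
    bvals = map_coordinates(outer.values, frac.T, order=1, mode="nearest")
    boundary = np.zeros(inner_spec.dims)
    boundary[idx[:, 0], idx[:, 1], idx[:, 2]] = bvals

    inner_maps = build_media_maps(structure, inner_spec, config)
    inner = solve(inner_maps, config, boundary=boundary)
    inner.metadata.update({
        "focused": True,
        "outer_dims": tuple(config.outer_dims),
        "outer_spacing": config.outer_spacing,
    })
    inner.label = "PB potential (focused inner grid)"
    return inner
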