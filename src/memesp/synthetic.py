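"""Synthetic pseudo-bilayers and analytic screened-Coulomb potentials.

The generator emulates the system the analyses were designed for: a planar
hexagonally packed leaflet pair of neutral zwitterionic pseudo-lipids
(2-point choline/phosphate dipoles) with a single anionic probe lipid whose
charged headgroup (net -3 e) protrudes a configurable distance into the
solvent.  Snapshot-to-snapshot variability is modelled by Gaussian
positional jitter, plus optional rare large-magnitude grid spikes that
exercise the robustness of the remedian average.

The closed-form Debye-Hueckel superposition potential serves as an exact
oracle for the finite-difference solver and for the downstream bulge,
similarity and geometry metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import COULOMB_KCAL, debye_kappa
from .grid import GridSpec, PotentialGrid
from .manifest import EnsembleManifest
from .structure import StructureModel

#: Fraction of voxels hit when a snapshot grid receives an outlier spike.
SPIKE_VOXEL_FRACTION = 1e-3


@dataclass
class DebyeHuckelParams:
    """Solvent model for the analytic screened-Coulomb potential.

    ``ion_exclusion_radius`` enters through the (1 + kappa*a) Debye-Hueckel
    denominator per source atom.
    """

    ionic_strength: float = 0.1       # mol/L, 1:1 electrolyte
    dielectric: float = 80.0          # solvent relative dielectric
    temperature: float = 296.0        # K
    ion_exclusion_radius: float = 2.0  # Å

    def __post_init__(self) -> None:
        for name in ("ionic_strength", "dielectric", "temperature", "ion_exclusion_radius"):
            if getattr(self, name) < 0 or (name != "ionic_strength" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")

    @property
    def kappa(self) -> float:
        """Inverse Debye length, 1/Å."""
        return debye_kappa(self.ionic_strength, self.dielectric, self.temperature)


@dataclass
class SyntheticBilayerSpec:
    """Parameters of the pseudo-bilayer generator.

    Defaults give an area per lipid of (sqrt(3)/2) * 8.4^2 ~ 61 Å^2 and a
    phosphate-to-phosphate leaflet separation of 38 Å, typical of a fluid
    POPC bilayer; the probe carries the net -3 e of a PtdIns(3)P headgroup.
    """

    lattice_constant: float = 8.4      # Å, hexagonal lattice spacing
    lipids_per_leaflet: int = 64
    leaflet_separation: float = 38.0   # Å between the two phosphate planes
    dipole_charge: float = 1.0         # e; choline +q above, phosphate -q at plane
    dipole_separation: float = 4.5     # Å along z
    probe_charge: float = -3.0         # e, net headgroup charge on P1
    probe_z_offset: float = 0.0        # Å, P1 protrusion above the phosphate plane
    probe_theta_deg: float = 44.3      # planted P1->C4 tilt vs +z
    probe_phi_deg: float = -26.9       # planted C3->C5 tilt vs +z (signed)
    fluctuation_sigma: float = 0.5     # Å per-atom Gaussian jitter per snapshot
    outlier_rate: float = 0.0          # probability a snapshot grid is spiked
    outlier_amplitude: float = 50.0    # kcal/mol/e added at spiked voxels
    seed: int = 0

    # headgroup internal geometry (Å)
    p1_c4_length: float = 4.5
    c3_c5_length: float = 2.8

    def __post_init__(self) -> None:
        if self.lattice_constant <= 0:
            raise ValueError("lattice constant must be > 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier rate must be in [0, 1)")
        if self.probe_charge > 0:
            raise ValueError("probe charge must be <= 0 for this system")
        if self.lipids_per_leaflet < 0:
            raise ValueError("lipids per leaflet must be >= 0")


def hexagonal_sites(n: int, a: float) -> np.ndarray:
    """First ``n`` sites of a hexagonal lattice, ordered by distance from the
    patch centroid so the patch is roughly round and site 0 is central."""
    if n == 0:
        return np.zeros((0, 2))
    m = int(math.ceil(math.sqrt(n))) + 2
    cols = np.arange(-m, m + 1)
    rows = np.arange(-m, m + 1)
    xx = cols[None, :] * a + (rows[:, None] % 2) * (a / 2.0)
    yy = np.broadcast_to(rows[:, None] * (a * math.sqrt(3) / 2.0), xx.shape)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
    return pts[order[:n]]


def generate_bilayer(spec: SyntheticBilayerSpec) -> StructureModel:
    """Build the pseudo-bilayer structure described by ``spec``.

    Both leaflets carry ``lipids_per_leaflet`` dipole pseudo-lipids; the
    central upper-leaflet site is replaced by the probe headgroup (P1 plus
    C3/C4/C5 ring markers).  Deterministic: no randomness is involved.
    """
    a = spec.lattice_constant
    z_up = spec.leaflet_separation / 2.0
    coords, charges, radii = [], [], []
    names, resnames, resids, leaflets = [], [], [], []
    phosphate = []
    resid = 0

    sites = hexagonal_sites(max(spec.lipids_per_leaflet, 1), a)
    for leaflet, zsign in ((1, 1.0), (-1, -1.0)):
        zp = zsign * z_up
        zn = zp + zsign * spec.dipole_separation
        for isite in range(spec.lipids_per_leaflet):
            if leaflet == 1 and isite == 0:
                continue  # central upper site belongs to the probe
            x, y = sites[isite]
            resid += 1
            # phosphate (-q) at the leaflet plane, choline (+q) toward solvent
            coords += [(x, y, zp), (x, y, zn)]
            charges += [-spec.dipole_charge, spec.dipole_charge]
            radii += [1.9, 2.0]
            names += ["P", "N"]
            resnames += ["POPC", "POPC"]
            resids += [resid, resid]
            leaflets += [leaflet, leaflet]
            phosphate += [True, False]

    # probe lipid at the central upper-leaflet site
    resid += 1
    x0, y0 = sites[0] if len(sites) else (0.0, 0.0)
    p1 = np.array([x0, y0, z_up + spec.probe_z_offset])
    th = math.radians(spec.probe_theta_deg)
    ph = math.radians(spec.probe_phi_deg)
    u_ring = np.array([math.sin(th), 0.0, math.cos(th)])
    c4 = p1 + spec.p1_c4_length * u_ring
    v = np.array([math.sin(ph), 0.0, math.cos(ph)])
    c3 = c4 - 0.5 * spec.c3_c5_length * v
    c5 = c4 + 0.5 * spec.c3_c5_length * v
    p3 = c4 + 2.6 * u_ring
    probe_atoms = [("P1", p1, spec.probe_charge, 1.9),
                   ("C3", c3, 0.0, 1.7),
                   ("C4", c4, 0.0, 1.7),
                   ("C5", c5, 0.0, 1.7),
                   ("P3", p3, 0.0, 1.9)]
    roles = {}
    for name, pos, q, r in probe_atoms:
        roles[name] = len(coords)
        coords.append(tuple(pos))
        charges.append(q)
        radii.append(r)
        names.append(name)
        resnames.append("PI3P")
        resids.append(resid)
        leaflets.append(1)
        phosphate.append(False)

    return StructureModel(
        coords=np.asarray(coords), charges=np.asarray(charges),
        radii=np.asarray(radii), names=np.asarray(names, dtype=object),
        resnames=np.asarray(resnames, dtype=object),
        resids=np.asarray(resids), roles=roles,
        popc_phosphates=np.asarray(phosphate, dtype=bool),
        leaflets=np.asarray(leaflets),
    )


def analytic_potential(structure: StructureModel, grid_spec: GridSpec,
                       params: DebyeHuckelParams | None = None,
                       r_min: float = 1e-3) -> PotentialGrid:
    """Screened-Coulomb superposition potential on a grid (kcal/mol/e).

    phi(r) = sum_i C q_i exp(-kappa (r_i - a)) / (eps (1 + kappa a) r_i)
    with C the Coulomb constant in kcal*Å/(mol*e^2) and ``a`` the ion
    exclusion radius.  Voxels closer than ``r_min`` to a source are clamped
    to the ``r_min`` value and counted in ``metadata['clamped_voxels']``.
    """
    params = params or DebyeHuckelParams()
    kappa = params.kappa
    pref = COULOMB_KCAL / (params.dielectric * (1.0 + kappa * params.ion_exclusion_radius))
    x, y, z = grid_spec.meshgrid()
    phi = np.zeros(grid_spec.dims, dtype=float)
    clamped = 0
    for pos, q in zip(structure.coords, structure.charges):
        if q == 0.0:
            continue
        r = np.sqrt((x - pos[0]) ** 2 + (y - pos[1]) ** 2 + (z - pos[2]) ** 2)
        nclip = int(np.count_nonzero(r < r_min))
        if nclip:
            clamped += nclip
            r = np.maximum(r, r_min)
        if kappa == 0.0:
            phi += pref * q / r
        else:
            phi += pref * q * np.exp(-kappa * (r - params.ion_exclusion_radius)) / r
    return PotentialGrid(spec=grid_spec, values=phi, label="analytic DH potential",
                         metadata={"clamped_voxels": clamped})


def perturb_structure(structure: StructureModel, sigma: float,
                      rng: np.random.Generator) -> StructureModel:
    """Gaussian positional jitter applied to every atom."""
    jitter = rng.normal(0.0, sigma, size=structure.coords.shape) if sigma > 0 else 0.0
    return replace(structure, coords=structure.coords + jitter)


def perturb_ensemble(structure: StructureModel, n: int,
                     spec: SyntheticBilayerSpec, grid_spec: GridSpec,
                     params: DebyeHuckelParams | None = None,
                     dt_ns: float = 0.1,
                     return_structures: bool = False):
    """Generate ``n`` snapshot grids from jittered copies of ``structure``.

    With probability ``spec.outlier_rate`` a snapshot grid receives an
    additive spike of ``spec.outlier_amplitude`` at a random 0.1% of its
    voxels.  Fully reproducible from ``spec.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or DebyeHuckelParams()
    rng = np.random.default_rng(spec.seed)
    grids, structures = [], []
    nvox = int(np.prod(grid_spec.dims))
    n_spike = max(1, round(SPIKE_VOXEL_FRACTION * nvox))
    for i in range(n):
        snap = perturb_structure(structure, spec.fluctuation_sigma, rng)
        grid = analytic_potential(snap, grid_spec, params)
        grid.label = f"snapshot {i:04d}"
        if spec.outlier_rate > 0 and rng.random() < spec.outlier_rate:
            idx = rng.choice(nvox, size=n_spike, replace=False)
            flat = grid.values.ravel()
            flat[idx] += spec.outlier_amplitude
            grid.metadata["spiked"] = True
        grids.append(grid)
        structures.append(snap)
    manifest = EnsembleManifest.from_grids(
        grids, times=[i * dt_ns for i in range(n)], alignment_tag="synthetic"
    )
    if return_structures:
        return manifest, structures
    return manifest
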