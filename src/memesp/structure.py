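"""Atomic structures with charges, radii and headgroup role tags.

A :class:`StructureModel` is the minimal structure the electrostatics and
geometry analyses need: coordinates (Å), partial charges (e), van der Waals
radii (Å), plus role tags for the probe-lipid headgroup atoms (P1, P3, C3,
C4, C5) and a flag marking the phosphate atom of each background (POPC)
lipid.  Structures are read from PQR files; role tags are inferred from atom
and residue names through a configurable role map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ROLE_TAGS = ("P1", "P3", "C3", "C4", "C5")

#: Default mapping: probe headgroup roles come from atom names within the
#: probe residue; any atom named P in a POPC residue is its phosphate.
DEFAULT_ROLE_MAP = {
    "probe_resnames": ("PI3P", "PIP", "PT3P"),
    "popc_resnames": ("POPC", "PC"),
    "roles": {"P1": "P1", "P3": "P3", "C3": "C3", "C4": "C4", "C5": "C5"},
    "popc_phosphate_names": ("P", "P8", "P31"),
}


class StructureError(ValueError):
    pass


@dataclass
class StructureModel:
    """Atoms with coordinates, charges, radii and role annotations."""

    coords: np.ndarray                 # (n, 3) Å
    charges: np.ndarray                # (n,) e
    radii: np.ndarray                  # (n,) Å
    names: np.ndarray                  # (n,) atom names
    resnames: np.ndarray               # (n,) residue names
    resids: np.ndarray                 # (n,) residue numbers
    roles: dict = field(default_factory=dict)        # role tag -> atom index
    popc_phosphates: np.ndarray | None = None        # (n,) bool
    leaflets: np.ndarray | None = None               # (n,) +1 upper / -1 lower

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        self.radii = np.asarray(self.radii, dtype=float).reshape(n)
        self.names = np.asarray(self.names, dtype=object).reshape(n)
        self.resnames = np.asarray(self.resnames, dtype=object).reshape(n)
        self.resids = np.asarray(self.resids, dtype=int).reshape(n)
        if self.popc_phosphates is None:
            self.popc_phosphates = np.zeros(n, dtype=bool)
        else:
            self.popc_phosphates = np.asarray(self.popc_phosphates, dtype=bool).reshape(n)
        if self.leaflets is not None:
            self.leaflets = np.asarray(self.leaflets, dtype=int).reshape(n)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def role_position(self, tag: str) -> np.ndarray:
        """Cartesian position of a tagged headgroup atom (e.g. ``"P1"``)."""
        if tag not in self.roles:
            raise StructureError(f"role tag {tag!r} is not present in this structure")
        return self.coords[self.roles[tag]]

    def infer_leaflets(self, midplane_z: float | None = None) -> None:
        """Assign leaflets by sign of z relative to the bilayer midplane."""
        if midplane_z is None:
            midplane_z = float(np.median(self.coords[:, 2]))
        self.leaflets = np.where(self.coords[:, 2] >= midplane_z, 1, -1)

    def assign_roles(self, role_map: dict | None = None) -> None:
        """Populate role tags and POPC phosphate flags from atom names."""
        rm = dict(DEFAULT_ROLE_MAP)
        if role_map:
            rm.update(role_map)
        probe_res = set(rm["probe_resnames"])
        popc_res = set(rm["popc_resnames"])
        name_to_role = {v: k for k, v in rm["roles"].items()}
        phos_names = set(rm["popc_phosphate_names"])
        self.roles = {}
        mask = np.zeros(len(self), dtype=bool)
        for i, (name, res) in enumerate(zip(self.names, self.resnames)):
            if res in probe_res and name in name_to_role:
                self.roles[name_to_role[name]] = i
            elif res in popc_res and name in phos_names:
                mask[i] = True
        self.popc_phosphates = mask


def read_pqr(path: str, role_map: dict | None = None) -> StructureModel:
    """Read a PQR file (via MDAnalysis) and annotate headgroup roles."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
    atoms = u.atoms
    model = StructureModel(
        coords=atoms.positions.astype(float),
        charges=atoms.charges.astype(float),
        radii=atoms.radii.astype(float),
        names=np.array([a.name for a in atoms], dtype=object),
        resnames=np.array([a.resname for a in atoms], dtype=object),
        resids=np.array([a.resid for a in atoms], dtype=int),
    )
    model.assign_roles(role_map)
    model.infer_leaflets()
    return model


def write_pqr(model: StructureModel, path: str) -> None:
    """Write a whitespace-delimited PQR file."""
    with open(path, "w") as fh:
        fh.write("REMARK generated by memesp\n")
        for i in range(len(model)):
            x, y, z = model.coords[i]
            fh.write(
                f"ATOM  {i + 1:5d} {str(model.names[i])[:4]:<4s} "
                f"{str(model.resnames[i])[:4]:<4s} {int(model.resids[i]):5d}    "
                f"{x:8.3f} {y:8.3f} {z:8.3f} {model.charges[i]:8.4f} {model.radii[i]:7.4f}\n"
            )
        fh.write("END\n")
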