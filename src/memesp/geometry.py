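"""Headgroup geometry: POPC phosphate reference plane, relative P1 z-height
and the inositol-ring tilt angles Theta and Phi.

Theta is the angle between the P1->C4 vector and the membrane normal (+z);
Phi is the angle between the C3->C5 vector and +z, signed by the
x-component of C3->C5 after rotating the frame about z so that P1->C4 lies
in the xz-plane with positive x (a z-rotation-invariant sign convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import StructureError, StructureModel


@dataclass
class GeometrySpec:
    """Reference-plane and angle conventions.

    ``exclusion_radius`` (Å) removes POPC phosphates laterally close to P1
    from the reference plane (they sit in the probe-induced depression);
    ``angle_convention`` is ``"vector-z"`` (plain vector-vs-z-axis angles,
    the default) or ``"from-plane"`` (both angles shifted by -90°, i.e.
    measured from the membrane plane).
    """

    exclusion_radius: float = 15.0
    leaflet: int | None = None          # +1 / -1; None = the P1 leaflet
    angle_convention: str = "vector-z"

    def __post_init__(self) -> None:
        if self.exclusion_radius < 0:
            raise ValueError("exclusion radius must be >= 0")
        if self.angle_convention not in ("vector-z", "from-plane"):
            raise ValueError(f"unknown angle convention {self.angle_convention!r}")


@dataclass
class TiltAngles:
    theta: float    # degrees, [0, 180] under the vector-z convention
    phi: float      # degrees, signed, (-180, 180]


def _p1_leaflet(structure: StructureModel) -> int:
    idx = structure.roles.get("P1")
    if idx is None:
        raise StructureError("role tag 'P1' is not present in this structure")
    if structure.leaflets is None:
        structure.infer_leaflets()
    return int(structure.leaflets[idx])


def popc_reference_z(structure: StructureModel, spec: GeometrySpec | None = None) -> float:
    """Mean z of same-leaflet POPC phosphates laterally farther than the
    exclusion radius from P1."""
    spec = spec or GeometrySpec()
    p1 = structure.role_position("P1")
    leaflet = spec.leaflet if spec.leaflet is not None else _p1_leaflet(structure)
    if structure.popc_phosphates is None or not structure.popc_phosphates.any():
        raise StructureError("structure has no flagged POPC phosphates")
    if structure.leaflets is None:
        structure.infer_leaflets()
    lateral = np.hypot(structure.coords[:, 0] - p1[0], structure.coords[:, 1] - p1[1])
    sel = (
        structure.popc_phosphates
        & (structure.leaflets == leaflet)
        & (lateral > spec.exclusion_radius)
    )
    if not sel.any():
        raise StructureError(
            f"no same-leaflet POPC phosphate beyond the {spec.exclusion_radius} Å "
            f"exclusion radius"
        )
    return float(structure.coords[sel, 2].mean())


def p1_relative_z(structure: StructureModel, spec: GeometrySpec | None = None) -> float:
    """Signed z of P1 relative to the POPC reference plane; positive means
    protruding toward the solvent on either leaflet."""
    spec = spec or GeometrySpec()
    p1 = structure.role_position("P1")
    ref = popc_reference_z(structure, spec)
    leaflet = spec.leaflet if spec.leaflet is not None else _p1_leaflet(structure)
    return float((p1[2] - ref) * leaflet)


def _angle_with_z(v: np.ndarray) -> float:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector has no tilt angle")
    return math.degrees(math.acos(max(-1.0, min(1.0, v[2] / n))))


def tilt_angles(structure: StructureModel, spec: GeometrySpec | None = None) -> TiltAngles:
    """Theta (P1->C4 vs +z) and signed Phi (C3->C5 vs +z)."""
    spec = spec or GeometrySpec()
    for tag in ("P1", "C3", "C4", "C5"):
        if tag not in structure.roles:
            raise StructureError(f"role tag {tag!r} is not present in this structure")
    p1 = structure.role_position("P1")
    c3 = structure.role_position("C3")
    c4 = structure.role_position("C4")
    c5 = structure.role_position("C5")
    w = c4 - p1
    v = c5 - c3
    theta = _angle_with_z(w)
    alpha = _angle_with_z(v)
    # rotate about z so w lies in the xz-plane with positive x, then sign phi
    psi = math.atan2(w[1], w[0])
    vx = math.cos(psi) * v[0] + math.sin(psi) * v[1]
    sign = -1.0 if vx < 0 else 1.0
    phi = sign * alpha
    if spec.angle_convention == "from-plane":
        theta -= 90.0
        phi -= 90.0
    return TiltAngles(theta=theta, phi=phi)
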