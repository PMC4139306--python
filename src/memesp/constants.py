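"""Physical constants and unit conversions.

All potentials in this package are stored in kcal/mol/e, all lengths in
Angstrom and all charges in elementary charges.  Conversions to kT/e and mV
are display helpers only.

Grid value arrays are indexed ``values[i, j, k]`` with ``i`` along x, ``j``
along y and ``k`` along z; serialized formats store x fastest, then y, then
z (Fortran order), see :data:`INDEX_ORDER`.
"""

from __future__ import annotations

import math

from scipy import constants as _sc

#: The single index-order convention used by every module: axis 0 = x,
#: axis 1 = y, axis 2 = z; on disk x varies fastest (Fortran order).
INDEX_ORDER = "xyz-fortran"

#: Coulomb constant in kcal * Angstrom / (mol * e^2):
#: phi(r) = COULOMB_KCAL * q / (eps_r * r) for a point charge in a uniform
#: dielectric.
COULOMB_KCAL: float = (
    _sc.e**2 / (4.0 * math.pi * _sc.epsilon_0) * _sc.N_A / (_sc.calorie * 1e3) * 1e10
)

#: Boltzmann constant in kcal/mol/K.
KB_KCAL: float = _sc.k * _sc.N_A / (_sc.calorie * 1e3)

#: Default temperature (K) for kT/e display conversions.
DEFAULT_TEMPERATURE: float = 296.0


def debye_kappa(ionic_strength: float, dielectric: float, temperature: float) -> float:
    """Inverse Debye screening length in 1/Angstrom.

    Parameters
    ----------
    ionic_strength : mol/L of a 1:1 electrolyte.
    dielectric : solvent relative dielectric constant.
    temperature : K.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0.0:
        return 0.0
    kappa_si = math.sqrt(
        2.0 * _sc.N_A * _sc.e**2 * ionic_strength * 1e3
        / (_sc.epsilon_0 * dielectric * _sc.k * temperature)
    )
    return kappa_si * 1e-10


def kcal_per_mol_e_to_kt_e(value: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a potential from kcal/mol/e to kT/e."""
    return value / (KB_KCAL * temperature)


def kcal_per_mol_e_to_mv(value: float) -> float:
    """Convert a potential from kcal/mol/e to millivolt."""
    # 1 kcal/mol/e = 4184 J/mol / (N_A e) volts
    return value * (_sc.calorie * 1e3) / (_sc.N_A * _sc.e) * 1e3
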