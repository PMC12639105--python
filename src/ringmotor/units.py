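"""Reduced-unit system and the mapping to nominal physical units.

The simulation uses reduced units throughout:

==========  =========================  =====================================
quantity    reduced unit               nominal physical equivalent
==========  =========================  =====================================
length      1 bead diameter            6 Angstrom (~ ssDNA rise per nt)
energy      1 k_B T at 300 K           0.593 kcal/mol
mass        1 bead mass                (arbitrary; sets the time unit)
time        tau = sqrt(m L^2 / k_BT)   not mapped; results are in steps
charge      1 elementary charge        1 e
==========  =========================  =====================================

Temperatures are expressed as multiples of 300 K (T = 1 is the production
temperature).  The Debye screening length and Bjerrum length are computed
from the physical salt concentration, temperature and dielectric constant
and then converted to reduced length via ``ANGSTROM_PER_LENGTH``.
"""

from __future__ import annotations

import math

#: Angstrom per reduced length unit.
ANGSTROM_PER_LENGTH = 6.0

#: e^2 / (4 pi eps0) expressed in (k_B T at 300 K) * Angstrom.
#: 1389.35 kJ/mol*A / (2.494 kJ/mol) = 557.0
COULOMB_KTA = 557.0

#: Avogadro-derived conversion: ions per A^3 for a 1 M solution.
_IONS_PER_A3_PER_M = 6.02214076e-4


def bjerrum_length(dielectric: float, temperature: float = 1.0) -> float:
    """Bjerrum length in reduced length units.

    Parameters
    ----------
    dielectric : relative dielectric constant of the solvent.
    temperature : reduced temperature (multiples of 300 K).
    """
    lb_angstrom = COULOMB_KTA / (dielectric * temperature)
    return lb_angstrom / ANGSTROM_PER_LENGTH


def debye_kappa(salt_molar: float, dielectric: float, temperature: float = 1.0) -> float:
    """Inverse Debye screening length (reduced units) for a 1:1 salt.

    kappa^2 = 8 pi l_B n  with n the number density of each ion species.
    """
    lb_angstrom = COULOMB_KTA / (dielectric * temperature)
    n = salt_molar * _IONS_PER_A3_PER_M
    kappa_per_angstrom = math.sqrt(8.0 * math.pi * lb_angstrom * n)
    return kappa_per_angstrom * ANGSTROM_PER_LENGTH


def angstrom_to_reduced(x: float) -> float:
    return x / ANGSTROM_PER_LENGTH


def reduced_to_angstrom(x: float) -> float:
    return x * ANGSTROM_PER_LENGTH
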