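"""Unit conventions and conversions.

Canonical internal units throughout the package:

* length            micrometres (um)
* 3D number density um^-3 (molecules per cubic micron)
* 2D number density um^-2
* 3D association constant um^3 (per molecule)
* 2D association constant um^2
* time              seconds

Molar quantities are accepted and emitted only at I/O boundaries; a 1 M
solution contains ``MOLAR_TO_PER_UM3`` molecules per cubic micron.  Keeping
per-molecule constants internally avoids Avogadro factors inside every
equilibrium expression.
"""

from __future__ import annotations

#: molecules per um^3 in a 1 M solution (N_A / 1e15)
MOLAR_TO_PER_UM3 = 6.02214076e8

#: micrometres per nanometre
NM_TO_UM = 1e-3


class InvalidParameterError(ValueError):
    """A physical parameter violated its domain (sign, units, range)."""


def molar_to_per_um3(c_molar: float) -> float:
    """Convert a concentration in mol/L to molecules per um^3."""
    return c_molar * MOLAR_TO_PER_UM3


def per_um3_to_molar(c_per_um3: float) -> float:
    """Convert molecules per um^3 to mol/L; exact inverse of molar_to_per_um3."""
    return c_per_um3 / MOLAR_TO_PER_UM3


def ka_molar_to_um3(ka_per_molar: float) -> float:
    """Convert a 3D association constant from M^-1 to um^3 per molecule."""
    return ka_per_molar / MOLAR_TO_PER_UM3


def ka_um3_to_molar(ka_um3: float) -> float:
    """Convert a 3D association constant from um^3 per molecule to M^-1."""
    return ka_um3 * MOLAR_TO_PER_UM3


def nm_to_um(length_nm: float) -> float:
    return length_nm * NM_TO_UM


def um_to_nm(length_um: float) -> float:
    return length_um / NM_TO_UM
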