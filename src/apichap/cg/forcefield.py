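"""Force-field constants and the screened-electrostatics closed forms.

Reduced units: energies in units of the native-contact well depth
(epsilon = 1), lengths in Å.  The simulation temperature T = 0.4 reduced
units is taken to correspond to ~300 K, which fixes the energy scale at
kB * 300 K / 0.4 ≈ 1.49 kcal/mol and thereby the electrostatic prefactor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chains import load_hydrophobicity_scale

# physical constants (SI)
_KB = 1.380649e-23          # J/K
_NA = 6.02214076e23         # 1/mol
_E_CHARGE = 1.602176634e-19  # C
_EPS0 = 8.8541878128e-12    # F/m

_KB_KCAL = _KB * _NA / 4184.0          # kcal/(mol K)
_COULOMB_KCAL = (_E_CHARGE ** 2 * _NA
                 / (4.0 * math.pi * _EPS0 * 1e-10 * 4184.0))  # kcal Å/mol e²


def debye_length(ionic_strength: float, temperature_K: float = 300.0,
                 dielectric: float = 80.0) -> float:
    """Debye screening length in Å for a 1:1 electrolyte.

    lambda_D = sqrt(eps0 * eps_r * kB * T / (2 * NA * e^2 * I)) with the
    ionic strength I in mol/L.  At I = 0.02 M, 300 K, water this is ~21.5 Å.
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    i_si = ionic_strength * 1000.0  # mol/m^3
    lam = math.sqrt(_EPS0 * dielectric * _KB * temperature_K
                    / (2.0 * _NA * _E_CHARGE ** 2 * i_si))
    return lam * 1e10


@dataclass
class ForceField:
    """Interaction constants, all in reduced energy units and Å."""

    eps_native: float = 1.0       # native-contact well depth (defines eps)
    eps_rep: float = 1.0          # excluded-volume strength
    sigma_rep: float = 4.0        # Å
    dielectric: float = 80.0
    ionic_strength: float = 0.02  # M
    temperature_K: float = 300.0  # used only for the Debye length mapping
    lambda_hp: float = 1.0        # hydrophobic interaction strength
    sigma_hp: float = 5.0         # Å; attraction truncated at 2*sigma_hp
    k_bond: float = 100.0         # eps/Å^2
    k_angle: float = 20.0         # eps/rad^2 (folded chains)
    k_dihedral: float = 1.0       # eps (folded chains)
    energy_scale_kcal: float = _KB_KCAL * 300.0 / 0.4  # kcal/mol per eps
    hydrophobicity_scale: dict = field(
        default_factory=load_hydrophobicity_scale)

    def __post_init__(self) -> None:
        if self.ionic_strength <= 0:
            raise ValueError("ionic_strength must be positive")
        for name in ("eps_native", "eps_rep", "lambda_hp", "k_bond",
                     "k_angle", "k_dihedral"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def debye_len(self) -> float:
        return debye_length(self.ionic_strength, self.temperature_K,
                            self.dielectric)

    @property
    def dh_prefactor(self) -> float:
        """Coulomb prefactor B in reduced-energy Å per unit charge pair."""
        return _COULOMB_KCAL / self.dielectric / self.energy_scale_kcal


def debye_huckel_energy(qi: float, qj: float, r: float,
                        ff: ForceField) -> float:
    """Screened Coulomb pair energy B*qi*qj*exp(-r/lambda_D)/r."""
    if r <= 0:
        raise ValueError("distance must be positive")
    if qi == 0.0 or qj == 0.0:
        return 0.0
    return ff.dh_prefactor * qi * qj * math.exp(-r / ff.debye_len) / r
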