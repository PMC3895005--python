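"""Physical constants and unit conversions.

The toolkit works internally in kcal/mol (energy), angstrom (length),
nanosecond (time), kelvin (temperature) and elementary charge.  Conductance
is the one quantity reported in SI-derived units (picosiemens); the explicit
converters for that live here so that every estimator obtains its constants
from a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, kcal/mol/K.
KB_KCALMOL_K = 0.0019872041

#: Elementary charge, coulomb.
E_CHARGE_C = 1.602176634e-19

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Thermochemical calorie: joule per kcal.
J_PER_KCAL = 4184.0

#: kcal/mol -> joule per particle.
KCALMOL_TO_J_PARTICLE = J_PER_KCAL / AVOGADRO

ANGSTROM_TO_M = 1e-10
NS_TO_S = 1e-9


@dataclass(frozen=True)
class UnitSystem:
    """Bundle of constants defining the working unit system.

    A single module-level instance (:data:`UNITS`) is shared by every
    estimator; constructing alternative systems is supported for testing.
    """

    kB: float = KB_KCALMOL_K
    e_charge: float = E_CHARGE_C
    kcalmol_to_J_per_particle: float = KCALMOL_TO_J_PARTICLE
    angstrom_to_m: float = ANGSTROM_TO_M
    ns_to_s: float = NS_TO_S

    def kbt(self, temperature: float) -> float:
        """Thermal energy kB*T in kcal/mol.

        Parameters
        ----------
        temperature : float
            Absolute temperature in kelvin; must be positive.
        """
        if not temperature > 0:
            raise ValueError(f"temperature must be positive, got {temperature}")
        return self.kB * temperature

    def beta(self, temperature: float) -> float:
        """Inverse thermal energy 1/(kB*T) in mol/kcal."""
        return 1.0 / self.kbt(temperature)

    def stiffness_in_kbt(self, k: float, temperature: float) -> float:
        """Express a harmonic stiffness (kcal/mol/A^2) in kBT/A^2."""
        if k < 0:
            raise ValueError(f"stiffness must be non-negative, got {k}")
        return k / self.kbt(temperature)

    def kcalmol_to_joule(self, energy: float) -> float:
        """Convert kcal/mol to joule per particle."""
        return energy * self.kcalmol_to_J_per_particle

    def joule_to_kcalmol(self, energy: float) -> float:
        """Convert joule per particle to kcal/mol."""
        return energy / self.kcalmol_to_J_per_particle


#: The default (and normally only) unit system.
UNITS = UnitSystem()


def kbt(temperature: float) -> float:
    """kB*T in kcal/mol for the default unit system."""
    return UNITS.kbt(temperature)


def beta(temperature: float) -> float:
    """1/(kB*T) in mol/kcal for the default unit system."""
    return UNITS.beta(temperature)


def stiffness_in_kbt(k: float, temperature: float) -> float:
    """Harmonic stiffness in kBT/A^2 for the default unit system."""
    return UNITS.stiffness_in_kbt(k, temperature)
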