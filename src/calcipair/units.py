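"""Fixed unit system and thermodynamic state.

The whole package works in a single unit system:

* length        : angstrom (A)
* time          : picosecond (ps)
* temperature   : kelvin (K)
* energy        : kJ/mol
* charge        : elementary charge (e)

``KB`` is Boltzmann's constant in kJ/mol/K and ``COULOMB`` is the Coulomb
prefactor e^2/(4 pi eps0) in kJ*A/mol, so that the interaction of two unit
charges at distance r (A) is ``COULOMB / r`` kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant, kJ/mol/K
KB = 0.008314463

#: Coulomb constant e^2 / (4 pi eps0), kJ * A / mol
COULOMB = 1389.35458

#: Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23


def molar_volume_angstrom3() -> float:
    """Volume per formula unit at 1 M concentration, in A^3.

    1 mol/L corresponds to one formula unit per
    ``1e27 A^3 / N_A ~= 1660 A^3`` (1 L = 1e27 A^3).
    """
    return 1e27 / AVOGADRO


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived inverse temperature.

    ``beta * kb * temperature == 1`` holds by construction.  The default
    temperature of 330 K is the simulation temperature used throughout the
    package (chosen to offset the known ~30 K shift of water properties in
    the underlying density functional).
    """

    temperature: float = 330.0
    kb: float = KB

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.kb <= 0:
            raise ValueError(f"kb must be positive, got {self.kb}")

    @property
    def kbt(self) -> float:
        """Thermal energy kB*T in kJ/mol."""
        return self.kb * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(kB*T) in mol/kJ."""
        return 1.0 / (self.kb * self.temperature)
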