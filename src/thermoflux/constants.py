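"""Physical constants (SI) used by the Gibbs-energy transforms.

All quantities are CODATA values; ``R_KJ`` is the gas constant expressed in
kJ mol^-1 K^-1 because the package works in kJ/mol throughout.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the physical constants entering the Debye-Hueckel
    limiting slope and the gas-constant prefactors."""

    R: float = 8.314462  # gas constant, J mol^-1 K^-1
    F: float = 96485.332  # Faraday constant, C mol^-1
    epsilon0: float = 8.8541878e-12  # vacuum permittivity, F m^-1
    N_A: float = 6.02214076e23  # Avogadro constant, mol^-1

    @property
    def R_kj(self) -> float:
        """Gas constant in kJ mol^-1 K^-1."""
        return self.R / 1000.0

    @property
    def k_B(self) -> float:
        """Boltzmann constant, J K^-1."""
        return self.R / self.N_A


CONSTANTS = PhysicalConstants()

R_KJ = CONSTANTS.R_kj
CELSIUS_OFFSET = 273.15
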