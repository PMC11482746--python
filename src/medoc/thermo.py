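"""Solution thermodynamic parameters.

All free energies in the package are in kcal/mol.  ``RT`` at the default
298.15 K is about 0.5925 kcal/mol; one pH unit therefore corresponds to
``RT * ln(10)`` ~= 1.364 kcal/mol of proton chemical potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Gas constant, kcal / (mol K).
R_KCAL = 1.9872e-3

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ThermoParams:
    temperature: float = 298.15  # kelvin
    R: float = R_KCAL

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.temperature

    def pka_to_energy(self, pka: float) -> float:
        """Standard deprotonation free energy of an isolated site, RT ln(10) pKa."""
        return self.RT * LN10 * pka

    def energy_to_pka(self, g: float) -> float:
        return g / (self.RT * LN10)


DEFAULT_THERMO = ThermoParams()

__all__ = ["R_KCAL", "LN10", "ThermoParams", "DEFAULT_THERMO"]
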