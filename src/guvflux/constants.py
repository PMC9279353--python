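"""Physical constants and temperature-dependent water chemistry.

All concentrations in this package are expressed in mol/cm^3 (so that
[H+] = 10^-pH / 1000), permeabilities in cm/s and flux densities in
mol/cm^2/s.  Temperatures are kelvin; the package default of 294.15 K
(21 degC) matches typical room-temperature vesicle experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

FARADAY = 96485.0  # C/mol
GAS_CONSTANT = 8.314  # J/mol/K
DEFAULT_TEMPERATURE = 294.15  # K (21 degC)

# Water autoionization: pKw = 13.995 at 298.15 K, van't Hoff slope from
# the standard ionization enthalpy of water (55.8 kJ/mol).
_PKW_25C = 13.995
_DELTA_H_W = 55800.0  # J/mol


def water_ion_product(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Ion product of water K_w in (mol/cm^3)^2 at the given temperature.

    Uses a van't Hoff extrapolation from the 25 degC literature value.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    ln_kw_molar = -_PKW_25C * math.log(10.0) + (_DELTA_H_W / GAS_CONSTANT) * (
        1.0 / 298.15 - 1.0 / temperature
    )
    return math.exp(ln_kw_molar) / 1e6  # (mol/L)^2 -> (mol/cm^3)^2


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of constants used by the electrochemistry routines."""

    F: float = FARADAY
    R: float = GAS_CONSTANT
    T: float = DEFAULT_TEMPERATURE
    K_w: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.K_w == 0.0:
            object.__setattr__(self, "K_w", water_ion_product(self.T))

    @property
    def RT_over_F(self) -> float:
        """Thermal voltage R*T/F in volts."""
        return self.R * self.T / self.F

    @property
    def nernst_slope(self) -> float:
        """ln(10)*R*T/F in volts per pH unit (~58.4 mV at 21 degC)."""
        return math.log(10.0) * self.RT_over_F
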