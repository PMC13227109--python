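"""Physical constants in the unit system used throughout the package.

Concentrations are nM, time is s, temperature is K, energies are kcal/mol
(enthalpies, free energies) or cal/(mol*K) (entropies) -- the units in which
transition-state parameters are conventionally printed in the enzymology
literature.
"""

from scipy import constants as _sc

#: Gas constant in cal/(mol*K).
R_CAL: float = _sc.R / _sc.calorie

#: Boltzmann constant over Planck constant, 1/(K*s) -- the Eyring prefactor
#: per kelvin (k_B*T/h = KB_OVER_H * T).
KB_OVER_H: float = _sc.k / _sc.h

#: Conversion: 1 uM expressed in nM (bimolecular rate constants are accepted
#: in uM^-1 s^-1 and converted to nM^-1 s^-1 on evaluation).
NM_PER_UM: float = 1.0e3

#: 0 degrees Celsius in kelvin.
ZERO_CELSIUS_K: float = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + ZERO_CELSIUS_K
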