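"""Physical constants and unit helpers.

Energies throughout the package are in kcal/mol, temperatures in kelvin.
The pH-coupling constant ln(10)*kT is always computed from the temperature
at run time, never hard-coded.
"""

import math

#: Molar gas constant in kcal/(mol*K) (CODATA R = 8.31446261815324 J/(mol*K)).
R_KCAL = 8.31446261815324 / 4184.0

#: Default absolute temperature (K) used when none is specified.
DEFAULT_TEMPERATURE = 298.15

LN10 = math.log(10.0)


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kcal/mol at the given temperature (K)."""
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature


def ln10_kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """ln(10)*kT in kcal/mol: the free-energy cost of one pH unit per proton."""
    return LN10 * kT(temperature)
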