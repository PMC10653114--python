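"""Physical constants and unit helpers.

All free energies are in kJ/mol, temperatures in Kelvin, pKa values in pK
units throughout the package. kcal/mol input is supported only through an
explicit conversion at the ingestion boundary.
"""

from __future__ import annotations

import math

#: Molar gas constant in kJ/(mol K).
GAS_CONSTANT: float = 0.0083144621

#: kcal -> kJ conversion factor.
KCAL_TO_KJ: float = 4.184

#: Default temperature (Kelvin) when a system's experimental temperature is
#: not supplied.
DEFAULT_TEMPERATURE: float = 298.15


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(R*T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (GAS_CONSTANT * temperature)


def rt_ln10(temperature: float) -> float:
    """R*T*ln(10) in kJ/mol — the free energy of one pK unit.

    At 298.15 K this is approximately 5.708 kJ/mol; it is always computed
    from the gas constant, never hard-coded.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT * temperature * math.log(10.0)
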