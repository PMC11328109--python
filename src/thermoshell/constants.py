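"""Physical constants and unit conversions shared across the package.

All internal temperatures are Kelvin; user-facing I/O is Celsius.
Energies are kJ mol^-1, heat capacities kJ K^-1 mol^-1.
"""

#: Gas constant in kJ K^-1 mol^-1.
R_KJ = 8.314462618e-3

#: Offset between the Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET
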