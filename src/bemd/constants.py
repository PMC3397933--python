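"""Package-wide physical constants and unit conventions.

Units everywhere: length nm, energy kJ/mol, time ps, temperature K.
"""

#: Boltzmann constant in kJ/mol/K.
KB = 0.0083144621

#: Default simulation temperature in K.
DEFAULT_TEMPERATURE = 300.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return KB * temperature
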