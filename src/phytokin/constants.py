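"""Physical constants (CODATA) used by the Eyring and Arrhenius formalisms.

These are fixed values, not user-configurable: every published comparison in
the thermal-processing literature assumes them.
"""

#: Universal gas constant, J/(mol*K)
R = 8.314

#: Boltzmann constant, J/K
KB = 1.380649e-23

#: Planck constant, J*s
H = 6.62607015e-34

#: Celsius -> Kelvin offset
KELVIN_OFFSET = 273.15


def celsius_to_kelvin(temp_c: float) -> float:
    """Convert a Celsius temperature to Kelvin."""
    return temp_c + KELVIN_OFFSET
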