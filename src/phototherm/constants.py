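"""Physical constants.

The gas constant is carried in calorie units because activation and folding
enthalpies in enzyme thermodynamics are conventionally reported in cal/mol.
"""

#: Gas constant, cal mol^-1 K^-1 (conventional 4-digit value used in
#: transition-state and unfolding analyses).
R_CAL = 1.987

#: Boltzmann constant, J K^-1 (CODATA exact).
KB_J = 1.380649e-23

#: Planck constant, J s (CODATA exact).
H_J = 6.62607015e-34

#: kB/h, s^-1 K^-1 — the transition-state-theory frequency prefactor per kelvin.
KB_OVER_H = KB_J / H_J

#: Offset between Celsius and Kelvin scales.
C_TO_K = 273.15


def celsius_to_kelvin(t_celsius):
    """Convert a temperature (scalar or array) from Celsius to Kelvin."""
    return t_celsius + C_TO_K
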