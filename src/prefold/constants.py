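"""Physical constants used throughout the package.

Coordinates are in Å everywhere; conversions to SI happen only inside the
PRE forward model. Energies are in kcal/mol unless a docstring says
otherwise.
"""

# gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872e-3

# Boltzmann constant per mole, cal mol^-1 K^-1 (for entropy bookkeeping)
KB_CAL = 1.9872

# SI constants (CODATA 2018) for the Solomon-Bloembergen prefactor
MU_0 = 1.25663706212e-6        # vacuum permeability, N A^-2
GAMMA_H = 2.6752218744e8       # 1H gyromagnetic ratio, rad s^-1 T^-1
G_E = 2.00231930436            # free-electron g-factor
MU_B = 9.2740100783e-24        # Bohr magneton, J T^-1
KB_SI = 1.380649e-23           # Boltzmann constant, J K^-1

ANGSTROM = 1e-10               # m
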