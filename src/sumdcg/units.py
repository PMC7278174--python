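"""Unit system and physical constants.

Every quantity in this package is expressed in the MD-typical unit set
angstrom (length), picosecond (time), atomic mass unit (mass),
kcal/mol (energy) and elementary charge (charge).  These units are not
mutually consistent, so two conversion factors appear wherever energies
meet masses and velocities.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 0.0019872041

#: Coulomb prefactor, kcal mol^-1 A e^-2 (vacuum permittivity).
COULOMB = 332.0637

#: 1 kcal/mol expressed in amu A^2 ps^-2.  Divides kinetic energy
#: computed from amu and A/ps into kcal/mol; multiplies force/mass
#: (kcal mol^-1 A^-1 / amu) into acceleration (A ps^-2).
KCAL_TO_AMU_A2_PS2 = 418.4
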