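"""Physical constants and unit conversions used throughout the package.

All real-space lengths are Angstrom, electron densities e/A^3, Laplacians
e/A^5, electrostatic potentials e/A, energies kJ/mol unless stated otherwise.
"""

# Bohr radius in Angstrom (CODATA)
BOHR_ANGSTROM = 0.52917721

# Conversion factors for density quantities between e/A^n and atomic units
A3_TO_AU = BOHR_ANGSTROM**3  # multiplies rho [e/A^3] -> a.u.
A5_TO_AU = BOHR_ANGSTROM**5  # multiplies laplacian [e/A^5] -> a.u.

# 1 hartree in kJ/mol
HARTREE_KJMOL = 2625.4996

# e^2 / (4 pi eps0) expressed so that (charge e) * (potential e/A) -> kJ/mol
COULOMB_KJMOL_ANG = 1389.3546
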