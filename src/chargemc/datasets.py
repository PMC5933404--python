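"""Published reference values from the experimental charge-density study of
(E)-5-phenylpent-1-enylboronic acid ("BOH2", C11H15BO2, space group Pbca).

These are the printed tables of that study — critical-point properties of
the covalent and intermolecular bonds with their sample standard deviations
(SSDs) over 20 deviating models, atomic charges, and dimer electrostatic
energies.  They serve as input data for worked examples and as ground truth
for validating the statistics and energy-density machinery of this package
on real published numbers; they are not produced by this package.

Units: distances A, rho e/A^3, Laplacian e/A^5, charges e, energies kJ/mol.
"""

from __future__ import annotations

import pandas as pd

# ---------------------------------------------------------------------------
# Covalent bond critical points: X, Y, d(X,Y), rho, SSD(rho), laplacian,
# SSD(lap), ellipticity, SSD(eps), bond class

_COVALENT_ROWS = [
    # aromatic ring C-C bonds
    ("C4", "C5", 1.3935, 2.184, 0.008, -20.7, 0.4, 0.21, 0.02, "aromatic"),
    ("C3", "C4", 1.3929, 2.18, 0.02, -20.3, 0.6, 0.222, 0.009, "aromatic"),
    ("C5", "C6", 1.3955, 2.11, 0.02, -19.5, 0.4, 0.25, 0.01, "aromatic"),
    ("C2", "C3", 1.3959, 2.11, 0.02, -19.1, 0.3, 0.20, 0.01, "aromatic"),
    ("C1", "C6", 1.3975, 2.166, 0.009, -19.8, 0.4, 0.235, 0.007, "aromatic"),
    ("C1", "C2", 1.4014, 2.17, 0.02, -19.3, 0.4, 0.20, 0.01, "aromatic"),
    # formally single C-C bonds
    ("C1", "C7", 1.5079, 1.70, 0.02, -11.5, 0.3, 0.019, 0.009, "single"),
    ("C7", "C8", 1.5340, 1.592, 0.007, -9.9, 0.2, 0.101, 0.008, "single"),
    ("C8", "C9", 1.5331, 1.62, 0.01, -9.9, 0.3, 0.15, 0.02, "single"),
    ("C9", "C10", 1.5001, 1.73, 0.01, -13.2, 0.3, 0.17, 0.01, "single"),
    # formal double bond
    ("C10", "C11", 1.3439, 2.28, 0.02, -21.6, 0.4, 0.334, 0.008, "double"),
    # bonds to boron and oxygen
    ("B1", "C11", 1.5614, 1.30, 0.02, -7.0, 1.0, 0.09, 0.03, "B-C"),
    ("B1", "O1", 1.3711, 1.35, 0.01, 19.8, 0.8, 0.002, 0.007, "B-O"),
    ("B1", "O2", 1.3762, 1.33, 0.02, 17.5, 0.9, 0.03, 0.02, "B-O"),
]

COVALENT_BOND_CPS = pd.DataFrame(
    _COVALENT_ROWS,
    columns=["atom_x", "atom_y", "d_xy", "rho", "ssd_rho", "laplacian",
             "ssd_laplacian", "ellipticity", "ssd_ellipticity", "bond_class"])


# ---------------------------------------------------------------------------
# Intermolecular contacts (hydrogen bonds first); occurrence out of 20
# deviating models

_CONTACT_ROWS = [
    ("O1", "H2O", 20, 1.824, 0.207, 0.005, 3.41, 0.08, "hbond"),
    ("O2", "H1O", 20, 1.767, 0.221, 0.007, 4.0, 0.2, "hbond"),
    ("H10", "O1", 20, 2.580, 0.055, 0.002, 0.801, 0.006, "contact"),
    ("O1", "H92", 20, 2.801, 0.0345, 0.0006, 0.489, 0.005, "contact"),
    ("H81", "H91", 13, 2.711, 0.0185, 0.0008, 0.256, 0.004, "intermittent"),
    ("H81", "C4", 20, 2.887, 0.0504, 0.0008, 0.580, 0.006, "contact"),
    ("H92", "H11", 17, 2.775, 0.0109, 0.0006, 0.176, 0.004, "intermittent"),
    ("H71", "H11", 20, 2.777, 0.0153, 0.0006, 0.227, 0.003, "contact"),
    ("H71", "H91", 20, 2.663, 0.0230, 0.0006, 0.307, 0.004, "contact"),
    ("C11", "H5", 20, 2.939, 0.0363, 0.0007, 0.417, 0.003, "contact"),
    ("O2", "H6", 20, 2.906, 0.026, 0.002, 0.368, 0.005, "contact"),
    ("C1", "H4", 13, 2.916, 0.0364, 0.0008, 0.452, 0.005, "ambiguous"),
    ("H71", "H5", 20, 2.262, 0.040, 0.002, 0.564, 0.007, "contact"),
    ("H72", "H3", 20, 2.376, 0.035, 0.002, 0.483, 0.004, "contact"),
    ("H2", "H4", 20, 2.793, 0.0146, 0.0005, 0.198, 0.006, "contact"),
    ("H2", "C3", 20, 2.972, 0.0353, 0.0006, 0.408, 0.005, "contact"),
    ("H2", "H4b", 17, 2.425, 0.0432, 0.0009, 0.528, 0.005, "ambiguous"),
]

INTERMOLECULAR_CPS = pd.DataFrame(
    _CONTACT_ROWS,
    columns=["atom_1", "atom_2", "occurrence", "d_12", "rho", "ssd_rho",
             "laplacian", "ssd_laplacian", "contact_class"])

# The strong O...H-O hydrogen bond used as the worked energy example
HBOND_O1_H2O = {"rho": 0.207, "laplacian": 3.41,
                "e_hb_published": 37.9, "ssd_e_hb": 0.9}
HBOND_O2_H1O = {"rho": 0.221, "laplacian": 4.0,
                "e_hb_published": 41.0, "ssd_e_hb": 2.0}


# ---------------------------------------------------------------------------
# Atomic charges: Q_topo with SSD, Q_val = N_val - P_val with e.s.d. and SSD

_CHARGE_ROWS = [
    ("C1", -0.093, 0.035, -0.017, 0.054, 0.067),
    ("C2", -0.048, 0.038, -0.208, 0.057, 0.054),
    ("C3", -0.262, 0.035, -0.128, 0.063, 0.036),
    ("C4", -0.116, 0.048, -0.112, 0.062, 0.047),
    ("C5", -0.197, 0.058, -0.227, 0.059, 0.059),
    ("C6", -0.160, 0.045, -0.175, 0.054, 0.059),
    ("C7", 0.020, 0.034, -0.112, 0.047, 0.057),
    ("C8", -0.012, 0.031, -0.25, 0.048, 0.051),
    ("C9", 0.026, 0.027, -0.241, 0.048, 0.051),
    ("C10", -0.024, 0.028, -0.238, 0.043, 0.052),
    ("C11", -0.823, 0.029, 0.228, 0.055, 0.059),
    ("H2", 0.094, 0.015, 0.129, 0.024, 0.019),
    ("H3", 0.126, 0.016, 0.090, 0.024, 0.021),
    ("H4", 0.068, 0.017, 0.064, 0.025, 0.024),
    ("H5", 0.136, 0.017, 0.144, 0.023, 0.019),
    ("H6", 0.110, 0.025, 0.131, 0.022, 0.027),
    ("H71", -0.005, 0.010, 0.069, 0.023, 0.021),
    ("H72", 0.003, 0.014, 0.054, 0.023, 0.024),
    ("H81", 0.060, 0.014, 0.159, 0.019, 0.020),
    ("H82", 0.005, 0.017, 0.136, 0.021, 0.025),
    ("H91", -0.009, 0.021, 0.126, 0.024, 0.027),
    ("H92", 0.043, 0.013, 0.163, 0.021, 0.026),
    ("H10", 0.054, 0.017, 0.157, 0.021, 0.020),
    ("H11", 0.067, 0.013, 0.022, 0.021, 0.023),
    ("H1O", 0.584, 0.012, 0.355, 0.015, 0.014),
    ("H2O", 0.561, 0.008, 0.325, 0.015, 0.010),
    ("O1", -1.326, 0.019, -0.241, 0.024, 0.025),
    ("O2", -1.291, 0.018, -0.237, 0.024, 0.020),
    ("B1", 2.409, 0.013, -0.171, 0.057, 0.048),
]

ATOMIC_CHARGES = pd.DataFrame(
    _CHARGE_ROWS,
    columns=["atom", "q_topo", "ssd_q_topo", "q_val", "esd_p_val",
             "ssd_p_val"])


# ---------------------------------------------------------------------------
# Dimer electrostatic energies; involutional operators carry weight 1/2 in
# the packing sum ("SSD full" over the full normal matrix, "SSD no Uij"
# with thermal parameters excluded from it)

_DIMER_ROWS = [
    ("-x, -y+2, -z", -62.2, 4.2, 5.1, True),
    ("-x+1/2, y-1/2, z", -37.2, 3.2, 2.7, False),
    ("-x+1, -y+2, -z", -16.5, 1.7, 1.7, True),
    ("-x+1/2, y-1/2, z (b)", -9.1, 3.0, 2.0, False),
    ("x-1, y, z", -1.1, 2.0, 1.7, False),
    ("-x+1/2, y-1/2, z (c)", 0.5, 2.4, 2.3, False),
    ("-x+2, y-1/2, -z+1/2", 2.4, 1.8, 1.2, False),
    ("x-1/2, y, -z+1/2", 6.2, 3.1, 2.3, False),
]

DIMER_ENERGIES = pd.DataFrame(
    _DIMER_ROWS,
    columns=["symmetry", "e_elec", "ssd_full", "ssd_no_uij", "involutional"])

# published packing totals over these dimers
PACKING_SUM = -77.7          # kJ/mol, involution half-weights applied
PACKING_SSD_FULL = 14.8      # kJ/mol
PACKING_SSD_NO_UIJ = 8.9     # kJ/mol

# basin integration bookkeeping of the published study
BASIN_DEFICIT = 0.47         # e missed out of 102 electrons, 29 basins
BASIN_N_ATOMS = 29
BASIN_TOTAL_ELECTRONS = 102
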