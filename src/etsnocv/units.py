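"""Unit conventions.

All internal quantities are atomic units (Hartree, Bohr).  XYZ input is in
Angstrom and converted on read; human-readable reports are printed in
kcal/mol.
"""

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903  # CODATA 2018
ANGSTROM_PER_BOHR = 0.529177210903
HARTREE_TO_KCALMOL = 627.5094740631


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR


def hartree_to_kcalmol(x):
    return x * HARTREE_TO_KCALMOL
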