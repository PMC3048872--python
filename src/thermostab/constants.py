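"""Physical constants and empirical parameter tables.

All internal thermodynamic arithmetic is done in kelvin and cal/mol so the
gas constant appears exactly once, here. Reporting layers convert to
degrees Celsius and kcal/mol.
"""

from __future__ import annotations

from types import MappingProxyType

#: Ideal gas constant, cal mol^-1 K^-1.
R_CAL = 1.9872

#: Additive offset between Celsius and kelvin scales.
CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c):
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k):
    return t_k - CELSIUS_OFFSET


# ---------------------------------------------------------------------------
# van der Waals radii for solvent-accessibility calculations (heavy atoms
# only; hydrogens are not modelled).  Values in angstrom.
VDW_RADII = MappingProxyType(
    {
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "S": 1.80,
    }
)

#: Default solvent probe radius (water), angstrom.
PROBE_RADIUS = 1.4

# Polarity classes used to split accessible surface area.  Carbon and
# sulfur surface counts as apolar; nitrogen and oxygen as polar.
APOLAR_ELEMENTS = frozenset({"C", "S"})
POLAR_ELEMENTS = frozenset({"N", "O"})


# ---------------------------------------------------------------------------
# Structure-energetics correlation coefficients.  Empirical linear relations
# mapping buried apolar/polar surface (angstrom^2) to the unfolding heat
# capacity change and to the unfolding enthalpy at the 60 degC reference
# temperature.  Units: cal mol^-1 K^-1 A^-2 for the heat-capacity pair and
# cal mol^-1 A^-2 for the enthalpy pair.
DCP_APOLAR_COEF = 0.45
DCP_POLAR_COEF = -0.26

DH60_APOLAR_COEF = -8.44
DH60_POLAR_COEF = 31.4

#: Reference temperature for the enthalpy correlation, degC.
DH_REFERENCE_CELSIUS = 60.0


# ---------------------------------------------------------------------------
# Per-residue accessible surface areas (angstrom^2) of X in an extended
# Gly-X-Gly tripeptide, split into apolar (C, S) and polar (N, O) classes,
# heavy-atom convention.  Used as the fully-unfolded reference state when
# forming delta-ASA values.
GXG_REFERENCE_ASA = MappingProxyType(
    {
        #        (apolar, polar)
        "ALA": (70.0, 43.0),
        "ARG": (79.0, 160.0),
        "ASN": (46.0, 102.0),
        "ASP": (50.0, 95.0),
        "CYS": (104.0, 36.0),
        "GLN": (55.0, 120.0),
        "GLU": (63.0, 108.0),
        "GLY": (32.0, 54.0),
        "HIS": (97.0, 71.0),
        "ILE": (141.0, 35.0),
        "LEU": (141.0, 34.0),
        "LYS": (122.0, 82.0),
        "MET": (157.0, 36.0),
        "PHE": (181.0, 34.0),
        "PRO": (122.0, 31.0),
        "SER": (50.0, 74.0),
        "THR": (78.0, 62.0),
        "TRP": (204.0, 51.0),
        "TYR": (152.0, 82.0),
        "VAL": (116.0, 36.0),
    }
)

ONE_TO_THREE = MappingProxyType(
    {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    }
)
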