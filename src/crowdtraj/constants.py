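"""Physical constants and unit bridges.

Internal units are nm (length), ps (time), amu (mass), kelvin (temperature).
Everything here is CODATA-2018; derived bridges are exact products of the
base constants so that unit round-trips are reproducible to machine precision.
"""

# --- base constants (SI) ---
KB_J_PER_K = 1.380649e-23          # Boltzmann constant, J/K (exact, SI 2019)
HBAR_J_S = 1.054571817e-34         # reduced Planck constant, J*s
AVOGADRO = 6.02214076e23           # 1/mol (exact)
AMU_KG = 1.66053906660e-27         # atomic mass unit, kg

# --- unit bridges ---
NM_M = 1e-9                        # nm -> m
PS_S = 1e-12                       # ps -> s
# 1 nm^2/ps = 1e-18 m^2 / 1e-12 s = 1e-6 m^2/s = 1e6 um^2/s
NM2_PER_PS_TO_UM2_PER_S = 1e6
M2_PER_S_TO_UM2_PER_S = 1e12
# 1 L = 1e-3 m^3 = 1e24 nm^3
NM3_PER_L = 1e24
GAS_CONSTANT_J_PER_MOL_K = KB_J_PER_K * AVOGADRO  # 8.31446...

# cubic-lattice self-interaction constant of the periodic-box (Yeh-Hummer)
# diffusion correction D0 = D_pbc + kB*T*XI / (6*pi*eta*L)
XI_CUBIC = 2.837297

# dynamic viscosity of water at 300 K, Pa*s (default for the finite-size term)
WATER_VISCOSITY_300K = 0.89e-3

# --- atomic data ---
# Bondi van der Waals radii, nm.  Unknown elements fall back to FALLBACK_RADIUS.
BONDI_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "F": 0.147,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
    "SE": 0.190,
}
FALLBACK_RADIUS_NM = 0.17

# average atomic masses, amu
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}
FALLBACK_MASS_AMU = 12.011

# average amino-acid residue mass (amu) used for single-bead (Calpha) chains
MEAN_RESIDUE_MASS_AMU = 110.0

# monoisotopic-ish average residue masses for the 20 standard residues (amu),
# used when a bead chain carries a real sequence
RESIDUE_MASSES = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09, "CYS": 103.14,
    "GLN": 128.13, "GLU": 129.12, "GLY": 57.05, "HIS": 137.14, "ILE": 113.16,
    "LEU": 113.16, "LYS": 128.17, "MET": 131.19, "PHE": 147.18, "PRO": 97.12,
    "SER": 87.08, "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}

# residue-class scheme for quinary-contact composition: H hydrophobic,
# P polar, C charged.  Overridable wherever it is consumed.
DEFAULT_RESIDUE_CLASSES = {
    "ASP": "C", "GLU": "C", "LYS": "C", "ARG": "C", "HIS": "C",
    "SER": "P", "THR": "P", "ASN": "P", "GLN": "P", "CYS": "P",
    "TYR": "P", "TRP": "P",
    "ALA": "H", "VAL": "H", "LEU": "H", "ILE": "H", "MET": "H",
    "PHE": "H", "PRO": "H", "GLY": "H",
}

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})
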