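"""Physical constants and composition tables.

All composition-derived quantities (dry volumes, masses, partial specific
volumes) are computed from the tables in this one file so that every number
entering the sphere-model volume bookkeeping and the hydrodynamic
calculations is auditable.

Units: masses in Da (g/mol), volumes in nm^3, radii in nm unless noted.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol

# Water at 20 degrees C, the reference solvent for s20,w.
WATER_VISCOSITY_20C = 1.002e-3  # Pa s
WATER_DENSITY_20C = 0.99823  # g/mL

# Hydration of glycoproteins used for the hydrated sphere model.
HYDRATION_G_PER_G = 0.3  # g water per g glycoprotein
WATER_DENSITY_HYDRATION = 1.0  # g/mL, for converting bound water mass to volume

# Conversion: volume (nm^3) of m grams per molecule at density rho (g/mL):
#   V = m / (rho * 1e-21 g/nm^3) / N_A  ->  V_nm3 = M_Da / (rho * 602.214)
NM3_PER_DA_AT_UNIT_DENSITY = 1.0 / 602.214076

# Average residue masses of the 20 amino acids, Da (residue = monomer - water).
RESIDUE_MASS = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16, "ASN": 114.10,
    "ASP": 115.09, "GLN": 128.13, "LYS": 128.17, "GLU": 129.12, "MET": 131.19,
    "HIS": 137.14, "PHE": 147.18, "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}

WATER_MASS = 18.02  # Da, added once per chain (terminal H and OH)

# Consensus crystallographic residue volumes, nm^3 (Chothia-type values as
# used in sphere-model scattering work).
RESIDUE_VOLUME = {
    "GLY": 0.0663, "ALA": 0.0915, "SER": 0.0991, "PRO": 0.1293, "VAL": 0.1386,
    "THR": 0.1221, "CYS": 0.1057, "LEU": 0.1679, "ILE": 0.1688, "ASN": 0.1352,
    "ASP": 0.1133, "GLN": 0.1611, "LYS": 0.1763, "GLU": 0.1408, "MET": 0.1708,
    "HIS": 0.1673, "PHE": 0.2034, "ARG": 0.1879, "TYR": 0.2036, "TRP": 0.2376,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Generic dehydrated sugar unit for simplified extended N-glycan stubs
# (hexose-like average over a complex-type oligosaccharide).
SUGAR_UNIT_MASS = 162.14  # Da
SUGAR_UNIT_VOLUME = 0.1706  # nm^3
GLYCAN_RESNAME = "GLC"

# Ions retained from coordinate files.
ION_MASS = {"CA": 40.08}
ION_VOLUME = {"CA": 0.0}

# Heavy-atom radii for solvent-accessible surface area, Angstrom
# (NACCESS/Chothia-style group radii; hydrogens implicit).
SASA_RADII_A = {
    "C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80,
    "CA": 1.74, "ZN": 1.39, "MG": 1.73, "FE": 1.65,
}
SASA_PROBE_A = 1.4
SASA_POINTS = 960

# Bead radius representing hydrated atomic elements in the sedimentation
# coefficient calculation.
HYDRO_BEAD_RADIUS_NM = 0.284

# Elemental average masses used for mass-weighted radii of gyration.
ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CA": 40.078, "ZN": 65.38, "MG": 24.305, "FE": 55.845,
}


def residue_vbar(resname: str) -> float:
    """Partial specific volume of one residue type, mL/g."""
    v = RESIDUE_VOLUME[resname] * 602.214076
    return v / RESIDUE_MASS[resname]
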