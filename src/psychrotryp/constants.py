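"""Physical constants and versioned data tables.

Everything a calculation normalizes against lives here: CODATA physical
constants, amino-acid residue masses (average and monoisotopic), pKa sets for
net-charge/pI work, van der Waals radii for surface calculations, and the
per-residue-type side-chain reference maxima used to turn raw side-chain SASA
into relative exposure. Tables carry a version string that reports embed for
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

DATA_TABLE_VERSIONS = {
    "residue_masses": "expasy-average-2018/monoisotopic-2018",
    "pka": "bjellqvist-1993, emboss-6",
    "vdw_radii": "bondi-1964-subset",
    "max_sidechain_sasa": "psychrotryp-gxg-extended-v1",
}


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants for transition-state (Eyring) kinetics, SI units.

    ``kappa`` is the transmission coefficient of the Eyring equation
    k = kappa * (k_B*T/h) * exp(-dG/(R*T)); 1 is the universal default.
    """

    R: float = 8.314462618  # gas constant, J/mol/K
    k_B: float = 1.380649e-23  # Boltzmann, J/K
    h: float = 6.62607015e-34  # Planck, J*s
    kappa: float = 1.0  # transmission coefficient, dimensionless

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.k_B > 0 and self.h > 0):
            raise ValueError("physical constants must be strictly positive")
        if not (0.0 < self.kappa <= 1.0):
            raise ValueError("kappa must lie in (0, 1]")


CODATA = PhysicalConstants()

CELSIUS_OFFSET = 273.15

WATER_AVERAGE = 18.01528  # Da, added once per free peptide
WATER_MONOISOTOPIC = 18.010565
DISULFIDE_H2_LOSS = 2.01565  # Da removed per oxidized S-S bond

# ExPASy average residue (i.e. water-free) masses, Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

MONOISOTOPIC_RESIDUE_MASS = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "E": 129.04259, "Q": 128.05858, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}

STANDARD_AA = frozenset(AVERAGE_RESIDUE_MASS)

# pKa sets for Henderson-Hasselbalch net charge. Keys: side chains by
# one-letter code plus "Nterm"/"Cterm". Basic groups (positive below pKa):
# K, R, H, Nterm. Acidic groups (negative above pKa): D, E, C, Y, Cterm.
PKA_TABLES = {
    "bjellqvist": {
        "Nterm": 7.50, "Cterm": 3.55,
        "K": 10.00, "R": 12.00, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,
    },
    "emboss": {
        "Nterm": 8.60, "Cterm": 3.60,
        "K": 10.80, "R": 12.50, "H": 6.50,
        "D": 3.90, "E": 4.10, "C": 8.50, "Y": 10.10,
    },
}

BASIC_GROUPS = ("K", "R", "H")
ACIDIC_GROUPS = ("D", "E", "C", "Y")

# United-atom van der Waals radii, Angstrom (hydrogens are ignored).
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}

DEFAULT_PROBE_RADIUS = 1.4  # Angstrom, water probe

# Side-chain solvent-accessible reference maxima, Angstrom^2, computed on
# extended Gly-X-Gly tripeptides (CCD ideal side chains, extended backbone)
# with this package's own surface parameters (960-point golden lattice,
# united-atom Bondi radii, 1.4 A probe) — see scripts/generate_reference_sasa.py.
# Self-consistency matters more than any published table here: relative
# exposure divides an observed side-chain SASA by these, so reference and
# observation must share radii and probe. Glycine has no side chain; its
# entry is the CA-proxy value from Gly-Gly-Gly.
MAX_SIDECHAIN_SASA = {
    "A": 47.6, "R": 185.7, "N": 102.2, "D": 101.1, "C": 81.9,
    "E": 129.0, "Q": 129.7, "G": 27.7, "H": 126.2, "I": 111.8,
    "L": 124.9, "K": 147.3, "M": 138.0, "F": 155.5, "P": 68.2,
    "S": 63.6, "T": 89.9, "W": 199.5, "Y": 172.0, "V": 97.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET
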