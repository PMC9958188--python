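"""Canonical heavy-atom compositions, masses, and partial charges.

The shipped TSV tables under ``rnpscore/data`` are generated from the
dictionaries in this module (see :func:`build_canonical_rna_table` /
:func:`build_canonical_protein_table` in :mod:`rnpscore.structures`).
Partial charges are AMBER-style approximate values; masses are IUPAC
standard atomic weights. The TSV file remains the single configurable
source of truth at run time.
"""

from __future__ import annotations

# IUPAC 2021 standard atomic weights (Da), heavy atoms only.
ELEMENT_MASS = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

RNA_CODES = ("A", "G", "C", "U")

# Full 5'-phosphate backbone: 12 heavy atoms per nucleotide.
RNA_BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
    "C3'", "O3'", "C2'", "O2'", "C1'",
)

RNA_BASE_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

RNA_BACKBONE_CHARGE = {
    "P": 1.1662, "OP1": -0.7760, "OP2": -0.7760, "O5'": -0.4989,
    "C5'": 0.0558, "C4'": 0.1065, "O4'": -0.3548, "C3'": 0.2022,
    "O3'": -0.5246, "C2'": 0.0670, "O2'": -0.6139, "C1'": 0.0394,
}

RNA_BASE_CHARGE = {
    "A": {"N9": -0.0251, "C8": 0.2006, "N7": -0.6073, "C5": 0.0515,
          "C6": 0.7009, "N6": -0.9019, "N1": -0.7615, "C2": 0.5875,
          "N3": -0.6997, "C4": 0.3053},
    "G": {"N9": 0.0492, "C8": 0.1374, "N7": -0.5709, "C5": 0.1744,
          "C6": 0.4770, "O6": -0.5597, "N1": -0.4787, "C2": 0.7657,
          "N2": -0.9672, "N3": -0.6323, "C4": 0.1222},
    "C": {"N1": -0.0484, "C2": 0.7538, "O2": -0.6252, "N3": -0.7584,
          "C4": 0.8185, "N4": -0.9530, "C5": -0.5215, "C6": 0.0053},
    "U": {"N1": 0.0418, "C2": 0.4687, "O2": -0.5477, "N3": -0.3549,
          "C4": 0.5952, "O4": -0.5761, "C5": -0.3635, "C6": -0.1126},
}

AMINO_CODES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

PROTEIN_BACKBONE_ATOMS = ("N", "CA", "C", "O")

PROTEIN_SIDECHAIN_ATOMS = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

PROTEIN_BACKBONE_CHARGE = {"N": -0.4157, "CA": 0.0337, "C": 0.5973, "O": -0.5679}

# Explicit charges for polar/charged side-chain atoms; apolar carbons and
# sulfurs fall back to the element defaults below.
_SIDECHAIN_CHARGE_OVERRIDES = {
    ("ARG", "NE"): -0.5295, ("ARG", "CZ"): 0.8076,
    ("ARG", "NH1"): -0.8627, ("ARG", "NH2"): -0.8627,
    ("ASN", "CG"): 0.7130, ("ASN", "OD1"): -0.5931, ("ASN", "ND2"): -0.9191,
    ("ASP", "CG"): 0.7994, ("ASP", "OD1"): -0.8014, ("ASP", "OD2"): -0.8014,
    ("CYS", "SG"): -0.3119,
    ("GLN", "CD"): 0.6951, ("GLN", "OE1"): -0.6086, ("GLN", "NE2"): -0.9407,
    ("GLU", "CD"): 0.8054, ("GLU", "OE1"): -0.8188, ("GLU", "OE2"): -0.8188,
    ("HIS", "ND1"): -0.3811, ("HIS", "NE2"): -0.5727,
    ("LYS", "NZ"): -0.3854,
    ("MET", "SD"): -0.2737,
    ("SER", "OG"): -0.6546,
    ("THR", "OG1"): -0.6761,
    ("TRP", "NE1"): -0.3418,
    ("TYR", "OH"): -0.5579,
}

_ELEMENT_DEFAULT_CHARGE = {"C": 0.0, "N": -0.6, "O": -0.55, "S": -0.2, "P": 1.1}


def element_of(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name (heavy atoms + H)."""
    stripped = atom_name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    first = stripped[0]
    if first in "0123456789":  # e.g. hydrogens like 1HB
        first = stripped.lstrip("0123456789")[0]
    if first == "H":
        return "H"
    if first in ELEMENT_MASS:
        return first
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


def sidechain_charge(residue: str, atom_name: str) -> float:
    override = _SIDECHAIN_CHARGE_OVERRIDES.get((residue, atom_name))
    if override is not None:
        return override
    return _ELEMENT_DEFAULT_CHARGE[element_of(atom_name)]
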