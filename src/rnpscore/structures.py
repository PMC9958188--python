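"""Structure ingestion, atom typing, and interface extraction.

Parses PDB coordinate files into protein/RNA residue units, attaches
(type id, mass, partial charge) annotations from tabular typing files,
and selects the interaction interface at a distance cutoff (default
6 Å, closed interval, heavy atoms, whole-unit membership).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata
from .errors import CompositionError, ParseError, TypingError

logger = logging.getLogger(__name__)

DEFAULT_INTERFACE_CUTOFF = 6.0


@dataclass
class AtomRecord:
    """One atom: PDB-convention name, element, Cartesian position in Å."""

    name: str
    element: str
    position: np.ndarray
    unit_index: int
    chain_id: str
    is_hydrogen: bool = False
    type_id: int | None = None
    mass: float | None = None
    charge: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    @property
    def typed(self) -> bool:
        return self.type_id is not None


@dataclass
class ResidueUnit:
    """A nucleotide or amino-acid residue with its atoms."""

    kind: Literal["nucleotide", "amino_acid"]
    type_code: str
    atoms: list[AtomRecord]
    chain_id: str
    seq_index: int

    def __post_init__(self):
        if self.kind == "nucleotide" and self.type_code not in chemdata.RNA_CODES:
            raise ValueError(f"nucleotide with non-RNA code {self.type_code!r}")
        if self.kind == "amino_acid" and self.type_code not in chemdata.AMINO_CODES:
            raise ValueError(f"amino acid with unknown code {self.type_code!r}")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in {self.type_code} {self.chain_id}{self.seq_index}"
            )

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        heavy = self.heavy_atoms()
        if not heavy:
            return np.empty((0, 3))
        return np.stack([a.position for a in heavy])

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_index)


@dataclass
class ComplexStructure:
    """One RNA-protein complex split into protein and RNA units."""

    protein_units: list[ResidueUnit]
    rna_units: list[ResidueUnit]
    source_id: str = ""

    def __post_init__(self):
        if not self.protein_units or not self.rna_units:
            raise CompositionError(
                f"{self.source_id or 'complex'}: needs at least one protein "
                f"and one RNA unit (got {len(self.protein_units)} protein, "
                f"{len(self.rna_units)} RNA)"
            )
        self.protein_units = sorted(self.protein_units, key=lambda u: u.key)
        self.rna_units = sorted(self.rna_units, key=lambda u: u.key)

    def units(self, molecule: str) -> list[ResidueUnit]:
        if molecule == "protein":
            return self.protein_units
        if molecule == "rna":
            return self.rna_units
        raise ValueError(f"unknown molecule {molecule!r}")

    def iter_units(self) -> Iterator[tuple[str, ResidueUnit]]:
        for u in self.rna_units:
            yield "rna", u
        for u in self.protein_units:
            yield "protein", u

    def heavy_coords(self, molecule: str) -> np.ndarray:
        coords = [u.heavy_coords() for u in self.units(molecule)]
        coords = [c for c in coords if len(c)]
        if not coords:
            return np.empty((0, 3))
        return np.concatenate(coords)

    def typed_heavy_atoms(self) -> list[AtomRecord]:
        out = []
        for _, unit in self.iter_units():
            out.extend(a for a in unit.heavy_atoms() if a.typed)
        return out


@dataclass
class AtomTypeTable:
    """Maps (residue/nucleotide code, atom name) to (type id, mass, charge)."""

    entries: dict[tuple[str, str], tuple[int, float, float]]
    molecule: Literal["rna", "protein"]

    def __post_init__(self):
        ids = sorted(tid for tid, _, _ in self.entries.values())
        if ids and ids != list(range(len(ids))):
            raise ValueError("type_ids must be contiguous from 0 and unique")
        for (code, name), (_, mass, _) in self.entries.items():
            if mass <= 0:
                raise ValueError(f"non-positive mass for ({code}, {name})")

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, code: str, atom_name: str) -> tuple[int, float, float] | None:
        return self.entries.get((code, atom_name))

    @classmethod
    def from_tsv(cls, path: str | Path, molecule: str) -> "AtomTypeTable":
        entries = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["residue_code", "atom_name", "type_id", "mass", "charge"]
            if header != expected:
                raise ParseError(f"{path}: expected columns {expected}, got {header}")
            for line in fh:
                if not line.strip():
                    continue
                code, name, tid, mass, charge = line.rstrip("\n").split("\t")
                entries[(code, name)] = (int(tid), float(mass), float(charge))
        return cls(entries=entries, molecule=molecule)

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(self.entries.items(), key=lambda kv: kv[1][0])
        with open(path, "w") as fh:
            fh.write("residue_code\tatom_name\ttype_id\tmass\tcharge\n")
            for (code, name), (tid, mass, charge) in rows:
                fh.write(f"{code}\t{name}\t{tid}\t{mass:.4f}\t{charge:.4f}\n")


def build_canonical_rna_table() -> AtomTypeTable:
    """Canonical 85-entry table: A,G,C,U heavy atoms with full 5'-phosphate."""
    entries = {}
    tid = 0
    for code in chemdata.RNA_CODES:
        for name in chemdata.RNA_BACKBONE_ATOMS + chemdata.RNA_BASE_ATOMS[code]:
            mass = chemdata.ELEMENT_MASS[chemdata.element_of(name)]
            if name in chemdata.RNA_BACKBONE_ATOMS:
                charge = chemdata.RNA_BACKBONE_CHARGE[name]
            else:
                charge = chemdata.RNA_BASE_CHARGE[code][name]
            entries[(code, name)] = (tid, mass, charge)
            tid += 1
    return AtomTypeTable(entries=entries, molecule="rna")


def build_canonical_protein_table() -> AtomTypeTable:
    """167-entry table over the 20 standard amino acids, heavy atoms only."""
    entries = {}
    tid = 0
    for code in chemdata.AMINO_CODES:
        for name in chemdata.PROTEIN_BACKBONE_ATOMS:
            entries[(code, name)] = (
                tid,
                chemdata.ELEMENT_MASS[chemdata.element_of(name)],
                chemdata.PROTEIN_BACKBONE_CHARGE[name],
            )
            tid += 1
        for name in chemdata.PROTEIN_SIDECHAIN_ATOMS[code]:
            entries[(code, name)] = (
                tid,
                chemdata.ELEMENT_MASS[chemdata.element_of(name)],
                chemdata.sidechain_charge(code, name),
            )
            tid += 1
    return AtomTypeTable(entries=entries, molecule="protein")


def default_table_path(molecule: str) -> Path:
    fname = {"rna": "rna_atom_types.tsv", "protein": "protein_atom_types.tsv"}[molecule]
    return Path(resources.files("rnpscore") / "data" / fname)


def load_default_tables() -> tuple[AtomTypeTable, AtomTypeTable]:
    """Load the packaged (rna_table, protein_table) pair."""
    return (
        AtomTypeTable.from_tsv(default_table_path("rna"), "rna"),
        AtomTypeTable.from_tsv(default_table_path("protein"), "protein"),
    )


def count_types(table: AtomTypeTable) -> int:
    """Number of (residue code, atom name) entries in a typing table."""
    return len(table)


# ---------------------------------------------------------------------------
# PDB parsing

_RNA_RES_NAMES = set(chemdata.RNA_CODES)
_AA_RES_NAMES = set(chemdata.AMINO_CODES)


def parse_pdb(path: str | Path, source_id: str | None = None) -> ComplexStructure:
    """Parse a PDB file into a ComplexStructure.

    Keeps heavy atoms of standard residues/nucleotides (hydrogens retained
    but flagged); resolves altlocs to highest occupancy; drops waters, ions
    and other heteroatoms. Raises ParseError / CompositionError.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises various exception types
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    keep = np.isin(atoms.res_name, sorted(_RNA_RES_NAMES | _AA_RES_NAMES))
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise CompositionError(f"{path}: no standard RNA or protein residues")

    protein_units: list[ResidueUnit] = []
    rna_units: list[ResidueUnit] = []
    unit_index = 0
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for beg, end in zip(starts[:-1], starts[1:]):
        res_name = atoms.res_name[beg]
        chain_id = str(atoms.chain_id[beg])
        seq_index = int(atoms.res_id[beg])
        records = []
        seen = set()
        for i in range(beg, end):
            name = str(atoms.atom_name[i])
            if name in seen:  # residual altloc duplicates
                continue
            seen.add(name)
            element = str(atoms.element[i]).strip().capitalize()
            if not element:
                element = chemdata.element_of(name)
            records.append(
                AtomRecord(
                    name=name,
                    element=element,
                    position=np.array(atoms.coord[i], dtype=np.float64),
                    unit_index=unit_index,
                    chain_id=chain_id,
                    is_hydrogen=(element == "H"),
                )
            )
        if res_name in _RNA_RES_NAMES:
            rna_units.append(
                ResidueUnit("nucleotide", res_name, records, chain_id, seq_index)
            )
        else:
            protein_units.append(
                ResidueUnit("amino_acid", res_name, records, chain_id, seq_index)
            )
        unit_index += 1

    if not protein_units or not rna_units:
        raise CompositionError(
            f"{path}: complex must contain both protein and RNA chains "
            f"(found {len(protein_units)} protein, {len(rna_units)} RNA units)"
        )
    return ComplexStructure(
        protein_units=protein_units,
        rna_units=rna_units,
        source_id=source_id or path.stem,
    )


def assign_types(
    complex_: ComplexStructure,
    rna_table: AtomTypeTable,
    protein_table: AtomTypeTable,
    unknown_policy: Literal["skip", "fail"] = "skip",
) -> ComplexStructure:
    """Attach (type_id, mass, charge) to every heavy atom in place.

    Heavy atoms absent from the table are dropped with a warning under
    ``skip`` or raise TypingError under ``fail``. Hydrogens are never typed.
    Returns the same (annotated) complex.
    """
    for molecule, table in (("rna", rna_table), ("protein", protein_table)):
        for unit in complex_.units(molecule):
            kept = []
            for atom in unit.atoms:
                if atom.is_hydrogen:
                    kept.append(atom)
                    continue
                entry = table.lookup(unit.type_code, atom.name)
                if entry is None:
                    if unknown_policy == "fail":
                        raise TypingError(
                            f"no table entry for ({unit.type_code}, {atom.name})"
                        )
                    logger.warning(
                        "skipping untyped atom (%s, %s) in %s%d",
                        unit.type_code, atom.name, unit.chain_id, unit.seq_index,
                    )
                    continue
                atom.type_id, atom.mass, atom.charge = entry
                kept.append(atom)
            unit.atoms = kept
    return complex_


# ---------------------------------------------------------------------------
# Interface extraction


@dataclass
class InterfaceUnit:
    unit: ResidueUnit
    molecule: Literal["rna", "protein"]
    min_partner_distance: float


@dataclass
class InterfaceSelection:
    """Units (from both molecules) within ``cutoff`` of the partner molecule."""

    entries: list[InterfaceUnit]
    cutoff: float

    def __post_init__(self):
        for e in self.entries:
            if e.min_partner_distance > self.cutoff:
                raise ValueError(
                    f"unit {e.unit.key} at {e.min_partner_distance:.3f} Å "
                    f"exceeds cutoff {self.cutoff}"
                )
        if self.entries:
            molecules = {e.molecule for e in self.entries}
            if molecules != {"rna", "protein"}:
                raise ValueError("nonempty interface must span both molecules")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def is_empty(self) -> bool:
        return not self.entries

    def units(self) -> list[ResidueUnit]:
        return [e.unit for e in self.entries]

    def unit_keys(self, molecule: str) -> set[tuple[str, int]]:
        return {e.unit.key for e in self.entries if e.molecule == molecule}


def extract_interface(
    complex_: ComplexStructure, cutoff: float = DEFAULT_INTERFACE_CUTOFF
) -> InterfaceSelection:
    """Select whole units with any heavy atom ≤ cutoff from the partner.

    Membership is per-unit over heavy atoms with a closed distance interval.
    Selection is ordered RNA units first (by chain, seq_index), then protein.
    An empty selection is returned (with a warning) when molecules are apart.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    trees = {
        mol: cKDTree(complex_.heavy_coords(mol)) for mol in ("rna", "protein")
    }
    partner = {"rna": "protein", "protein": "rna"}
    entries: list[InterfaceUnit] = []
    for molecule in ("rna", "protein"):
        tree = trees[partner[molecule]]
        for unit in complex_.units(molecule):
            coords = unit.heavy_coords()
            if not len(coords):
                continue
            dmin = float(np.min(tree.query(coords)[0]))
            if dmin <= cutoff:
                entries.append(InterfaceUnit(unit, molecule, dmin))
    if not entries:
        logger.warning(
            "%s: empty interface at %.2f Å cutoff", complex_.source_id, cutoff
        )
    return InterfaceSelection(entries=entries, cutoff=cutoff)
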