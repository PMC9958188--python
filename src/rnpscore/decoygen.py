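"""Synthetic fixtures: toy RNA-protein complexes and rigid-body decoy sets.

Replaces the external docking pipeline with deterministic rigid-body
perturbation of the RNA partner, so decoys come with exact ligand-RMSD
labels and the whole scoring pipeline is testable offline.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chemdata
from .errors import QuotaError
from .structures import AtomRecord, ComplexStructure, ResidueUnit


# ---------------------------------------------------------------------------
# Toy complex construction

# Approximate nucleotide template in a local frame (Å). Names cover the
# backbone plus the glycosidic nitrogen and two ring atoms, all present in
# the canonical typing table; geometry is idealized, not chemically exact.
_NT_TEMPLATE = {
    "P": (-2.3, 1.9, 0.0),
    "OP1": (-3.5, 2.6, 0.5),
    "OP2": (-2.4, 1.9, -1.5),
    "O5'": (-1.0, 2.6, 0.4),
    "C5'": (0.2, 2.0, 0.9),
    "C4'": (1.2, 1.5, -0.1),
    "O4'": (1.0, 0.1, -0.3),
    "C3'": (1.2, 2.2, -1.5),
    "O3'": (2.4, 2.9, -1.7),
    "C2'": (1.2, 1.0, -2.4),
    "O2'": (2.2, 1.1, -3.4),
    "C1'": (1.4, -0.2, -1.5),
    # glycosidic nitrogen placed toward the helix axis
    "GN": (0.9, -1.5, -1.9),
    "RING1": (1.4, -2.6, -2.2),
    "RING2": (-0.4, -1.8, -2.0),
}

# atom names for GN/RING1/RING2 per base code (all in the 85-entry table)
_NT_RING_NAMES = {
    "A": ("N9", "C8", "C4"),
    "G": ("N9", "C8", "C4"),
    "C": ("N1", "C6", "C2"),
    "U": ("N1", "C6", "C2"),
}

# Extended-strand residue template: backbone + CB (ALA) or backbone + CB,
# OG (SER); all names covered by the protein table.
_AA_TEMPLATE = {
    "N": (-1.2, 0.8, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.2, 0.9, 0.3),
    "O": (1.2, 2.1, 0.1),
    "CB": (0.1, -0.9, -1.2),
}
_AA_EXTRA = {"SER": {"OG": (1.2, -1.7, -1.3)}}

_HELIX_TWIST = np.deg2rad(32.7)
_HELIX_RISE = 2.81
_HELIX_RADIUS = 4.0


def _rotation_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_toy_complex(seed: int, n_nt: int, n_aa: int) -> ComplexStructure:
    """Deterministic toy complex: helical RNA strand + extended peptide.

    The peptide is placed so the minimum intermolecular heavy-atom
    distance lands between 3 and 5 Å; every unit carries all frame-anchor
    atoms and only typing-table atom names.
    """
    if n_nt < 2 or n_aa < 2:
        raise ValueError("need at least 2 nucleotides and 2 residues")
    rng = np.random.default_rng(seed)

    base_codes = [("A", "G", "C", "U")[i % 4] for i in range(n_nt)]
    rna_units = []
    for i, code in enumerate(base_codes):
        R = _rotation_z(i * _HELIX_TWIST)
        offset = np.array([_HELIX_RADIUS, 0.0, i * _HELIX_RISE])
        jitter = rng.normal(0.0, 0.03, size=(len(_NT_TEMPLATE), 3))
        atoms = []
        names = list(_NT_TEMPLATE)
        gn, ring1, ring2 = _NT_RING_NAMES[code]
        rename = {"GN": gn, "RING1": ring1, "RING2": ring2}
        for j, tmpl_name in enumerate(names):
            pos = R @ (np.asarray(_NT_TEMPLATE[tmpl_name]) + offset) + jitter[j]
            name = rename.get(tmpl_name, tmpl_name)
            atoms.append(
                AtomRecord(
                    name=name,
                    element=chemdata.element_of(name),
                    position=pos,
                    unit_index=i,
                    chain_id="R",
                )
            )
        rna_units.append(ResidueUnit("nucleotide", code, atoms, "R", i + 1))

    aa_codes = [("ALA", "SER")[i % 2] for i in range(n_aa)]
    protein_units = []
    for i, code in enumerate(aa_codes):
        offset = np.array([12.0, 0.5 * (1 if i % 2 else -1), i * 3.8])
        jitter = rng.normal(0.0, 0.03, size=(8, 3))
        atoms = []
        template = dict(_AA_TEMPLATE)
        template.update(_AA_EXTRA.get(code, {}))
        for j, (name, local) in enumerate(template.items()):
            pos = np.asarray(local) + offset + jitter[j]
            atoms.append(
                AtomRecord(
                    name=name,
                    element=chemdata.element_of(name),
                    position=pos,
                    unit_index=n_nt + i,
                    chain_id="P",
                )
            )
        protein_units.append(ResidueUnit("amino_acid", code, atoms, "P", i + 1))

    complex_ = ComplexStructure(
        protein_units=protein_units,
        rna_units=rna_units,
        source_id=f"toy_s{seed}_n{n_nt}_a{n_aa}",
    )
    # slide the peptide along +x so the closest contact sits at 4 Å
    rna = complex_.heavy_coords("rna")
    prot = complex_.heavy_coords("protein")
    dmin = np.min(np.linalg.norm(rna[:, None] - prot[None], axis=2))
    shift = np.array([4.0 - dmin, 0.0, 0.0])
    for unit in complex_.protein_units:
        for atom in unit.atoms:
            atom.position = atom.position + shift
    return complex_


# ---------------------------------------------------------------------------
# Rigid-body perturbation


def _axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=np.float64)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if abs(angle_rad) > 1e-12:
            raise ValueError("zero axis with nonzero angle")
        return np.eye(3)
    x, y, z = axis / n
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


@dataclass
class RigidTransform:
    axis: np.ndarray
    angle_deg: float
    translation: np.ndarray

    def matrix(self) -> np.ndarray:
        return _axis_angle_matrix(self.axis, np.deg2rad(self.angle_deg))


def perturb_rigid(
    complex_: ComplexStructure, transform: RigidTransform
) -> ComplexStructure:
    """Rotate the RNA about its heavy-atom centroid, then translate.

    Protein coordinates are untouched (bit-identical to the input).
    """
    decoy = copy.deepcopy(complex_)
    centroid = complex_.heavy_coords("rna").mean(axis=0)
    R = transform.matrix()
    t = np.asarray(transform.translation, dtype=np.float64)
    pure_translation = abs(transform.angle_deg) < 1e-15
    for unit in decoy.rna_units:
        for atom in unit.atoms:
            if pure_translation:
                # keep translation-only decoys exact (RMSD == |t| bitwise)
                atom.position = atom.position + t
            else:
                atom.position = R @ (atom.position - centroid) + centroid + t
    return decoy


def ligand_rmsd(native: ComplexStructure, decoy: ComplexStructure) -> float:
    """RMSD over RNA heavy atoms, no superposition (pose difference)."""
    a = native.heavy_coords("rna")
    b = decoy.heavy_coords("rna")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Stratified decoy sets


@dataclass
class DecoySpec:
    n_decoys: int
    max_translation: float = 12.0
    max_rotation: float = 60.0
    rmsd_bins: list[tuple[float, float, int]] = field(default_factory=list)
    seed: int = 0
    max_attempts_per_decoy: int = 2000

    def __post_init__(self):
        if self.rmsd_bins:
            if sum(q for _, _, q in self.rmsd_bins) != self.n_decoys:
                raise ValueError("bin quotas must sum to n_decoys")
            spans = sorted((lo, hi) for lo, hi, _ in self.rmsd_bins)
            for (lo1, hi1), (lo2, _) in zip(spans, spans[1:]):
                if lo2 < hi1:
                    raise ValueError("rmsd bins overlap")


@dataclass
class DecoyRecord:
    decoy_id: str
    structure: ComplexStructure
    transform: RigidTransform
    ligand_rmsd: float


@dataclass
class DecoySet:
    native: ComplexStructure
    decoys: list[DecoyRecord]
    spec: DecoySpec


def _sample_transform(rng: np.random.Generator, spec: DecoySpec) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, spec.max_rotation)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = spec.max_translation * rng.uniform(0.0, 1.0) ** (1.0 / 3.0)
    return RigidTransform(axis=axis, angle_deg=angle, translation=radius * direction)


def generate_decoy_set(native: ComplexStructure, spec: DecoySpec) -> DecoySet:
    """Rejection-sample rigid decoys until every RMSD-bin quota is met."""
    rng = np.random.default_rng(spec.seed)
    bins = spec.rmsd_bins or [(0.0, float("inf"), spec.n_decoys)]
    decoys: list[DecoyRecord] = []
    idx = 0
    for lo, hi, quota in bins:
        produced = 0
        attempts = 0
        budget = spec.max_attempts_per_decoy * max(quota, 1)
        while produced < quota:
            if attempts >= budget:
                raise QuotaError(
                    f"bin [{lo}, {hi}) quota {quota} infeasible after "
                    f"{attempts} attempts (max_translation="
                    f"{spec.max_translation}, max_rotation={spec.max_rotation})"
                )
            attempts += 1
            transform = _sample_transform(rng, spec)
            decoy = perturb_rigid(native, transform)
            lrmsd = ligand_rmsd(native, decoy)
            if lo <= lrmsd < hi:
                decoys.append(
                    DecoyRecord(
                        decoy_id=f"decoy_{idx:04d}",
                        structure=decoy,
                        transform=transform,
                        ligand_rmsd=lrmsd,
                    )
                )
                produced += 1
                idx += 1
    return DecoySet(native=native, decoys=decoys, spec=spec)


# ---------------------------------------------------------------------------
# PDB round-trip


def write_pdb(complex_: ComplexStructure, path: str | Path) -> None:
    """Write the complex as minimal ATOM records (PDB fixed columns)."""
    lines = []
    serial = 1
    for _, unit in _pdb_unit_iter(complex_):
        res_name = unit.type_code
        for atom in unit.atoms:
            name = atom.name
            # PDB alignment: element right-justified in columns 13-14
            field_ = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = atom.position
            lines.append(
                f"ATOM  {serial:5d} {field_:<4s} {res_name:<3s} "
                f"{unit.chain_id}{unit.seq_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_unit_iter(complex_: ComplexStructure):
    for unit in complex_.rna_units:
        yield "rna", unit
    for unit in complex_.protein_units:
        yield "protein", unit


def write_decoy_set(decoy_set: DecoySet, out_dir: str | Path) -> Path:
    """Write native + decoys as PDB files plus a manifest CSV; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pdb(decoy_set.native, out_dir / "native.pdb")
    rows = ["decoy_id,path,rx,ry,rz,angle_deg,tx,ty,tz,ligand_rmsd"]
    for rec in decoy_set.decoys:
        fname = f"{rec.decoy_id}.pdb"
        write_pdb(rec.structure, out_dir / fname)
        ax, t = rec.transform.axis, rec.transform.translation
        rows.append(
            f"{rec.decoy_id},{fname},{ax[0]:.6f},{ax[1]:.6f},{ax[2]:.6f},"
            f"{rec.transform.angle_deg:.6f},{t[0]:.6f},{t[1]:.6f},{t[2]:.6f},"
            f"{rec.ligand_rmsd:.6f}"
        )
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
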