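"""Assessment metrics: RMSD, protein superposition, interface RMSD,
top-N success rates at the 4.0 Å native-likeness threshold, and a
simplified intermolecular hydrogen-bond detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegeneracyError,
    EmptyInputError,
    PairingError,
    UndefinedMetricError,
)
from .structures import ComplexStructure, extract_interface

logger = logging.getLogger(__name__)

SUCCESS_THRESHOLD = 4.0
DEFAULT_TOP_N = (1, 5, 10, 20, 30, 40, 50)
HBOND_DONOR_ACCEPTOR_MAX = 3.35
HBOND_H_ACCEPTOR_MAX = 2.7

PROTEIN_BACKBONE = ("N", "CA", "C", "O")


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation over paired coordinates (no superposition)."""
    a = np.asarray(coords_a, dtype=np.float64)
    b = np.asarray(coords_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or len(a) < 1:
        raise PairingError(
            f"coordinate lists must be equal-length (N,3) arrays, "
            f"got {a.shape} vs {b.shape}"
        )
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector
    fit_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto reference (Kabsch).

    Reflections are forbidden: the returned rotation is proper (det = +1).
    """
    mob = np.asarray(mobile, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise PairingError(f"paired (N,3) arrays required, got {mob.shape}, {ref.shape}")
    if len(mob) < 3:
        raise DegeneracyError("superposition needs at least 3 atom pairs")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    cov = mob_c.T @ ref_c
    U, S, Vt = np.linalg.svd(cov)
    # degenerate geometry: all points collinear/coincident leaves the
    # rotation about the degenerate axis undetermined
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise DegeneracyError("degenerate (collinear or coincident) coordinates")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    fitted = mob @ R.T + t
    return SuperpositionResult(rotation=R, translation=t, fit_rmsd=rmsd(fitted, ref))


def _paired_unit_coords(
    native: ComplexStructure,
    decoy: ComplexStructure,
    molecule: str,
    unit_keys: set[tuple[str, int]] | None = None,
    atom_names: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom coordinate pairs matched by (chain, seq_index, atom name)."""
    decoy_units = {u.key: u for u in decoy.units(molecule)}
    nat_pts, dec_pts, missing = [], [], []
    for unit in native.units(molecule):
        if unit_keys is not None and unit.key not in unit_keys:
            continue
        partner = decoy_units.get(unit.key)
        if partner is None:
            missing.append(f"{molecule} unit {unit.key}")
            continue
        for atom in unit.heavy_atoms():
            if atom_names is not None and atom.name not in atom_names:
                continue
            other = partner.atom(atom.name)
            if other is None or other.is_hydrogen:
                missing.append(f"{molecule} {unit.key} atom {atom.name}")
                continue
            nat_pts.append(atom.position)
            dec_pts.append(other.position)
    if missing:
        raise PairingError(
            f"atom correspondence failed for {len(missing)} atoms: "
            + ", ".join(missing[:5])
            + ("..." if len(missing) > 5 else "")
        )
    if not nat_pts:
        raise PairingError(f"no paired atoms for molecule {molecule}")
    return np.stack(nat_pts), np.stack(dec_pts)


def interface_rmsd(
    native: ComplexStructure,
    decoy: ComplexStructure,
    cutoff: float = 6.0,
    superpose_atoms: str = "heavy",
) -> float:
    """Interface RMSD after superposing the decoy protein onto the native's.

    Interface units are defined on the NATIVE at ``cutoff``; the optimal
    rigid transform fitted on protein atoms (all heavy or backbone-only)
    is applied to the whole decoy; the RMSD runs over heavy atoms of the
    native-interface units of both molecules.
    """
    selection = extract_interface(native, cutoff)
    if selection.is_empty:
        raise UndefinedMetricError(
            f"{native.source_id}: native interface empty at {cutoff} Å"
        )
    atom_names = PROTEIN_BACKBONE if superpose_atoms == "backbone" else None
    nat_prot, dec_prot = _paired_unit_coords(
        native, decoy, "protein", atom_names=atom_names
    )
    sup = superpose(dec_prot, nat_prot)

    pairs = []
    for molecule in ("rna", "protein"):
        keys = selection.unit_keys(molecule)
        if keys:
            pairs.append(_paired_unit_coords(native, decoy, molecule, unit_keys=keys))
    nat = np.concatenate([p[0] for p in pairs])
    dec = np.concatenate([p[1] for p in pairs])
    return rmsd(nat, sup.apply(dec))


# ---------------------------------------------------------------------------
# Success-rate bookkeeping


@dataclass
class RankedDecoy:
    decoy_id: str
    score: float
    irmsd: float


@dataclass
class ComplexReport:
    """Decoys of one complex, ranked best score first."""

    complex_id: str
    ranked: list[RankedDecoy]

    def best_irmsd_in_top(self, n: int) -> float:
        if len(self.ranked) < n:
            logger.warning(
                "%s: only %d decoys for top-%d", self.complex_id, len(self.ranked), n
            )
        head = self.ranked[:n]
        return min(r.irmsd for r in head)


def success_rate(
    reports: list[ComplexReport], n: int, threshold: float = SUCCESS_THRESHOLD
) -> float:
    """Fraction of complexes whose N best-scored decoys contain a decoy
    with interface RMSD ≤ threshold (closed interval)."""
    if not reports:
        raise EmptyInputError("no complex reports")
    hits = sum(1 for r in reports if r.best_irmsd_in_top(n) <= threshold)
    return hits / len(reports)


@dataclass
class EvaluationReport:
    reports: list[ComplexReport]
    threshold: float = SUCCESS_THRESHOLD
    top_n: tuple[int, ...] = DEFAULT_TOP_N
    success: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.success:
            self.success = {
                n: success_rate(self.reports, n, self.threshold) for n in self.top_n
            }

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_complexes": len(self.reports),
            "success_at_n": {str(n): v for n, v in self.success.items()},
            "lowest_irmsd_in_top": {
                r.complex_id: {str(n): r.best_irmsd_in_top(n) for n in self.top_n}
                for r in self.reports
            },
        }


# ---------------------------------------------------------------------------
# Hydrogen bonds (simplified distance-only detector)

# N/O atoms that carry at least one polar hydrogen (proline backbone N
# excluded; 5'-terminal variants not modelled).
_PROTEIN_DONORS = {
    ("*", "N"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("SER", "OG"), ("THR", "OG1"),
    ("TRP", "NE1"), ("TYR", "OH"),
}
_RNA_DONORS = {
    ("*", "O2'"),
    ("A", "N6"), ("C", "N4"), ("G", "N1"), ("G", "N2"), ("U", "N3"),
}
_PROTEIN_ACCEPTORS = {
    ("*", "O"),
    ("ASN", "OD1"), ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLN", "OE1"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}
_RNA_ACCEPTORS = {
    ("*", "OP1"), ("*", "OP2"), ("*", "O5'"), ("*", "O4'"),
    ("*", "O3'"), ("*", "O2'"),
    ("A", "N1"), ("A", "N3"), ("A", "N7"),
    ("G", "O6"), ("G", "N3"), ("G", "N7"),
    ("C", "O2"), ("C", "N3"), ("U", "O2"), ("U", "O4"),
}


def _in_class(table: set, code: str, name: str) -> bool:
    return ("*", name) in table or (code, name) in table


@dataclass
class HydrogenBond:
    donor: tuple[str, str, int, str]  # (molecule, chain, seq_index, atom)
    acceptor: tuple[str, str, int, str]
    donor_acceptor_distance: float
    hydrogen_acceptor_distance: float | None  # None when no H present

    def __post_init__(self):
        if self.donor_acceptor_distance > HBOND_DONOR_ACCEPTOR_MAX:
            raise ValueError("donor-acceptor distance exceeds maximum")
        if (
            self.hydrogen_acceptor_distance is not None
            and self.hydrogen_acceptor_distance > HBOND_H_ACCEPTOR_MAX
        ):
            raise ValueError("hydrogen-acceptor distance exceeds maximum")


def _polar_atoms(complex_, molecule, donors, acceptors):
    out = []
    for unit in complex_.units(molecule):
        hydrogens = [a for a in unit.atoms if a.is_hydrogen]
        for atom in unit.heavy_atoms():
            is_don = _in_class(donors, unit.type_code, atom.name)
            is_acc = _in_class(acceptors, unit.type_code, atom.name)
            if not (is_don or is_acc):
                continue
            attached = [
                h.position for h in hydrogens
                if np.linalg.norm(h.position - atom.position) < 1.25
            ]
            out.append((unit, atom, is_don, is_acc, attached))
    return out


def find_hbonds(complex_: ComplexStructure) -> list[HydrogenBond]:
    """Intermolecular (RNA<->protein) hydrogen bonds by distance criteria.

    A pair is reported iff donor-acceptor ≤ 3.35 Å and, when the donor has
    an explicit hydrogen, min H-acceptor ≤ 2.7 Å; without hydrogens the
    heavy-atom criterion alone applies (hydrogen distance reported None).
    """
    rna = _polar_atoms(complex_, "rna", _RNA_DONORS, _RNA_ACCEPTORS)
    prot = _polar_atoms(complex_, "protein", _PROTEIN_DONORS, _PROTEIN_ACCEPTORS)
    bonds = []
    for (mol_d, side_d), (mol_a, side_a) in (
        (("rna", rna), ("protein", prot)),
        (("protein", prot), ("rna", rna)),
    ):
        for unit_d, atom_d, is_don, _, hs in side_d:
            if not is_don:
                continue
            for unit_a, atom_a, _, is_acc, _ in side_a:
                if not is_acc:
                    continue
                dist = float(np.linalg.norm(atom_d.position - atom_a.position))
                if dist > HBOND_DONOR_ACCEPTOR_MAX:
                    continue
                h_dist = None
                if hs:
                    h_dist = float(
                        min(np.linalg.norm(h - atom_a.position) for h in hs)
                    )
                    if h_dist > HBOND_H_ACCEPTOR_MAX:
                        continue
                bonds.append(
                    HydrogenBond(
                        donor=(mol_d, unit_d.chain_id, unit_d.seq_index, atom_d.name),
                        acceptor=(mol_a, unit_a.chain_id, unit_a.seq_index, atom_a.name),
                        donor_acceptor_distance=dist,
                        hydrogen_acceptor_distance=h_dist,
                    )
                )
    return bonds
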