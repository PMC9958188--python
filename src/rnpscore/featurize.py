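"""Local coordinate frames and voxel-grid featurization.

Each interface nucleotide/residue gets a right-handed orthonormal frame
anchored on its backbone geometry; the whole complex is then binned into
a 32 Å cube (1 Å voxels) per unit, accumulating occupancy, mass and
charge channels. Grids are invariant under global rigid motion of the
complex because binning happens in frame-local coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegeneracyError, EmptyInputError, FrameError
from .structures import (
    AtomTypeTable,
    ComplexStructure,
    InterfaceSelection,
    ResidueUnit,
    assign_types,
    extract_interface,
)

logger = logging.getLogger(__name__)

DEFAULT_GRID_SIZE = 32
DEFAULT_VOXEL_EDGE = 1.0
DEFAULT_MAX_UNITS = 128

# Virtual-CB coefficients (ideal tetrahedral geometry) used for glycine:
# CB = ca + A*(b x c) + B*b + C*c with b = ca - n, c = c_atom - ca.
_VCB_A, _VCB_B, _VCB_C = -0.58273431, 0.56802827, -0.54067466

_PURINES = {"A", "G"}


@dataclass
class LocalFrame:
    """Origin (C1'/CA) plus right-handed orthonormal axes X, Y, Z."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def rotation(self) -> np.ndarray:
        """Columns are the frame axes; maps local -> global."""
        return np.column_stack([self.X, self.Y, self.Z])

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.origin) @ self.rotation()

    def validate(self, tol: float = 1e-9) -> None:
        R = self.rotation()
        if not np.allclose(R.T @ R, np.eye(3), atol=tol):
            raise ValueError("frame axes are not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > tol:
            raise ValueError("frame is not right-handed")


def _anchor_positions(unit: ResidueUnit) -> tuple[np.ndarray, ...]:
    """Return (origin, a1, a3, a4) positions for the frame construction."""
    if unit.kind == "nucleotide":
        glyco_n = "N9" if unit.type_code in _PURINES else "N1"
        names = ("C1'", glyco_n, "O5'", "C5'")
        found = [unit.atom(n) for n in names]
        if any(a is None for a in found):
            missing = [n for n, a in zip(names, found) if a is None]
            raise FrameError(
                f"{unit.type_code} {unit.chain_id}{unit.seq_index}: "
                f"missing anchor atom(s) {missing}"
            )
        return tuple(a.position for a in found)

    names = ("CA", "CB", "O", "C")
    ca, cb, o, c = (unit.atom(n) for n in names)
    if cb is None and unit.type_code == "GLY":
        n = unit.atom("N")
        if ca is None or c is None or n is None:
            raise FrameError(
                f"GLY {unit.chain_id}{unit.seq_index}: cannot build virtual CB"
            )
        b = ca.position - n.position
        cvec = c.position - ca.position
        cb_pos = ca.position + _VCB_A * np.cross(b, cvec) + _VCB_B * b + _VCB_C * cvec
    elif cb is not None:
        cb_pos = cb.position
    else:
        cb_pos = None
    if ca is None or cb_pos is None or o is None or c is None:
        missing = [n for n, a in zip(names, (ca, cb, o, c)) if a is None]
        raise FrameError(
            f"{unit.type_code} {unit.chain_id}{unit.seq_index}: "
            f"missing anchor atom(s) {missing}"
        )
    return ca.position, cb_pos, o.position, c.position


def build_frame(unit: ResidueUnit) -> LocalFrame:
    """Build the per-unit local frame.

    x = r_anchor1 - r_origin; y = midpoint(r_anchor3, r_anchor4) - r_origin;
    z = x × y; X = x/|x|; Z = z/|z|; Y = Z × X. Anchor1 is the glycosidic
    nitrogen (N9/N1) for nucleotides and CB (virtual for glycine) for
    residues; origin is C1'/CA; anchors 3/4 are O5',C5' / O,C.
    """
    origin, a1, a3, a4 = _anchor_positions(unit)
    x = a1 - origin
    y = 0.5 * (a3 + a4) - origin
    z = np.cross(x, y)
    nx, nz = np.linalg.norm(x), np.linalg.norm(z)
    if nx < 1e-12 or nz < 1e-12:
        raise DegeneracyError(
            f"{unit.type_code} {unit.chain_id}{unit.seq_index}: "
            "collinear or coincident anchor atoms"
        )
    X = x / nx
    Z = z / nz
    Y = np.cross(Z, X)
    return LocalFrame(origin=np.array(origin, dtype=np.float64), X=X, Y=Y, Z=Z)


@dataclass
class VoxelGrid:
    """3-channel cube: occupancy count, summed mass (Da), summed charge (e)."""

    channels: np.ndarray  # (3, n, n, n)
    voxel_edge: float = DEFAULT_VOXEL_EDGE

    @property
    def occupancy(self) -> np.ndarray:
        return self.channels[0]

    @property
    def mass(self) -> np.ndarray:
        return self.channels[1]

    @property
    def charge(self) -> np.ndarray:
        return self.channels[2]


def voxelize(
    frame: LocalFrame,
    positions: np.ndarray,
    masses: np.ndarray,
    charges: np.ndarray,
    grid_size: int = DEFAULT_GRID_SIZE,
    voxel_edge: float = DEFAULT_VOXEL_EDGE,
) -> VoxelGrid:
    """Bin atoms into the frame-centered cube.

    Local coordinates c are binned at index floor(c/voxel + half) per axis
    (half-open bins); atoms with any |c| >= half-extent are ignored.
    """
    half = grid_size / 2.0
    channels = np.zeros((3, grid_size, grid_size, grid_size), dtype=np.float64)
    positions = np.asarray(positions, dtype=np.float64)
    if len(positions) == 0:
        return VoxelGrid(channels=channels, voxel_edge=voxel_edge)
    local = frame.to_local(positions) / voxel_edge
    idx = np.floor(local + half).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < grid_size), axis=1)
    # exclude atoms exactly on the +half boundary (floor would give grid_size)
    inside &= np.all(local < half, axis=1)
    ii, jj, kk = idx[inside].T
    np.add.at(channels[0], (ii, jj, kk), 1.0)
    np.add.at(channels[1], (ii, jj, kk), np.asarray(masses)[inside])
    np.add.at(channels[2], (ii, jj, kk), np.asarray(charges)[inside])
    return VoxelGrid(channels=channels, voxel_edge=voxel_edge)


@dataclass
class ComplexTensor:
    """Stacked per-unit voxel grids: (3, L, n, n, n) with padding mask."""

    data: np.ndarray  # float32, shape (3, L, n, n, n)
    mask: np.ndarray  # uint8, shape (L,)
    unit_order: list[tuple[str, str, int]]  # (molecule, chain_id, seq_index)

    @property
    def n_units(self) -> int:
        return int(self.mask.sum())

    @property
    def L(self) -> int:
        return self.data.shape[1]

    @property
    def grid_size(self) -> int:
        return self.data.shape[2]


def _complex_atom_arrays(
    complex_: ComplexStructure,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    atoms = complex_.typed_heavy_atoms()
    if not atoms:
        return np.empty((0, 3)), np.empty(0), np.empty(0)
    pos = np.stack([a.position for a in atoms])
    mass = np.array([a.mass for a in atoms])
    charge = np.array([a.charge for a in atoms])
    return pos, mass, charge


def assemble_tensor(
    selection: InterfaceSelection,
    complex_: ComplexStructure,
    L: int = DEFAULT_MAX_UNITS,
    grid_size: int = DEFAULT_GRID_SIZE,
    voxel_edge: float = DEFAULT_VOXEL_EDGE,
) -> ComplexTensor:
    """Stack per-unit voxel grids of the interface into a padded tensor.

    Unit order is RNA units (chain, seq_index) then protein units; each
    unit's grid accumulates atoms of the WHOLE complex falling in its box.
    If more than L units are featurizable, the L with smallest
    min_partner_distance are kept (ties broken by unit order).
    """
    if selection.is_empty:
        raise EmptyInputError("cannot assemble a tensor from an empty interface")

    featurizable = []
    for order_idx, entry in enumerate(selection.entries):
        try:
            frame = build_frame(entry.unit)
        except (FrameError, DegeneracyError) as exc:
            logger.warning("dropping unit from tensor: %s", exc)
            continue
        featurizable.append((order_idx, entry, frame))
    if not featurizable:
        raise EmptyInputError("no interface unit yields a valid frame")

    if len(featurizable) > L:
        logger.warning(
            "truncating %d interface units to L=%d by partner distance",
            len(featurizable), L,
        )
        featurizable = sorted(
            featurizable, key=lambda t: (t[1].min_partner_distance, t[0])
        )[:L]
        featurizable.sort(key=lambda t: t[0])  # restore unit order

    pos, mass, charge = _complex_atom_arrays(complex_)
    data = np.zeros((3, L, grid_size, grid_size, grid_size), dtype=np.float32)
    mask = np.zeros(L, dtype=np.uint8)
    unit_order = []
    for slot, (_, entry, frame) in enumerate(featurizable):
        grid = voxelize(frame, pos, mass, charge, grid_size, voxel_edge)
        data[:, slot] = grid.channels.astype(np.float32)
        mask[slot] = 1
        unit_order.append((entry.molecule, entry.unit.chain_id, entry.unit.seq_index))
    return ComplexTensor(data=data, mask=mask, unit_order=unit_order)


def featurize_structure(
    complex_: ComplexStructure,
    rna_table: AtomTypeTable,
    protein_table: AtomTypeTable,
    cutoff: float = 6.0,
    L: int = DEFAULT_MAX_UNITS,
    grid_size: int = DEFAULT_GRID_SIZE,
    voxel_edge: float = DEFAULT_VOXEL_EDGE,
    unknown_policy: Literal["skip", "fail"] = "skip",
    allow_empty: bool = False,
) -> ComplexTensor:
    """Full pipeline: type assignment -> interface -> tensor.

    Reduced setups should shrink ``grid_size`` while scaling ``voxel_edge``
    up so the physical extent (grid_size * voxel_edge) still covers the
    interface neighborhood. With ``allow_empty``, a structure whose
    molecules make no contact at the cutoff yields an all-zero tensor
    (mask all zero) instead of raising.
    """
    assign_types(complex_, rna_table, protein_table, unknown_policy)
    selection = extract_interface(complex_, cutoff)
    if selection.is_empty and allow_empty:
        return empty_tensor(L=L, grid_size=grid_size)
    return assemble_tensor(
        selection, complex_, L=L, grid_size=grid_size, voxel_edge=voxel_edge
    )


def empty_tensor(L: int = DEFAULT_MAX_UNITS, grid_size: int = DEFAULT_GRID_SIZE) -> ComplexTensor:
    """All-zero tensor encoding a contact-free pose."""
    return ComplexTensor(
        data=np.zeros((3, L, grid_size, grid_size, grid_size), dtype=np.float32),
        mask=np.zeros(L, dtype=np.uint8),
        unit_order=[],
    )
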