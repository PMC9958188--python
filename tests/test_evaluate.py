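import copy

import numpy as np
import pytest

from rnpscore.decoygen import RigidTransform, perturb_rigid
from rnpscore.errors import (
    DegeneracyError,
    EmptyInputError,
    PairingError,
    UndefinedMetricError,
)
from rnpscore.evaluate import (
    ComplexReport,
    EvaluationReport,
    HydrogenBond,
    RankedDecoy,
    find_hbonds,
    interface_rmsd,
    rmsd,
    success_rate,
    superpose,
)
from rnpscore.structures import (
    AtomRecord,
    ComplexStructure,
    ResidueUnit,
    extract_interface,
)

from .conftest import random_rigid, transform_complex

# ---------------------------------------------------------------------------
# rmsd


def test_rmsd_identical_zero():
    coords = np.random.default_rng(0).normal(size=(20, 3))
    assert rmsd(coords, coords) == 0.0


def test_rmsd_uniform_translation():
    coords = np.random.default_rng(1).normal(size=(15, 3))
    assert rmsd(coords, coords + np.array([3.0, 4.0, 0.0])) == pytest.approx(
        5.0, abs=1e-12
    )


def test_rmsd_matches_double_loop_oracle():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(50, 3))
    b = rng.normal(size=(50, 3))
    total = 0.0
    for i in range(50):  # independent summation order, scalar accumulation
        for k in range(3):
            total += (a[i, k] - b[i, k]) ** 2
    assert rmsd(a, b) == pytest.approx(np.sqrt(total / 50), abs=1e-12)


def test_rmsd_symmetry_and_triangle():
    rng = np.random.default_rng(3)
    a, b, c = (rng.normal(size=(12, 3)) for _ in range(3))
    assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-15)
    assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-12


def test_rmsd_length_mismatch():
    with pytest.raises(PairingError):
        rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


# ---------------------------------------------------------------------------
# superposition


def test_superpose_exact_recovery():
    rng = np.random.default_rng(4)
    ref = rng.normal(size=(30, 3)) * 5
    Q, t = random_rigid(rng)
    mobile = ref @ Q.T + t  # ref rotated; superpose must invert it
    res = superpose(mobile, ref)
    assert res.fit_rmsd < 1e-9
    np.testing.assert_allclose(res.rotation.T @ res.rotation, np.eye(3), atol=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_superpose_mirror_proper_rotation():
    rng = np.random.default_rng(5)
    ref = rng.normal(size=(25, 3)) * 4
    mirrored = ref * np.array([-1.0, 1.0, 1.0])
    res = superpose(mirrored, ref)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
    assert res.fit_rmsd > 0.1


def test_superpose_optimality_random_search():
    rng = np.random.default_rng(6)
    ref = rng.normal(size=(20, 3)) * 3
    mobile = ref + rng.normal(0, 0.5, size=(20, 3))
    best = superpose(mobile, ref).fit_rmsd
    for _ in range(1000):
        Q, t = random_rigid(rng)
        assert best <= rmsd(mobile @ Q.T + t, ref) + 1e-12


def test_superpose_degenerate_collinear():
    line = np.outer(np.arange(5, dtype=float), [1.0, 0, 0])
    with pytest.raises(DegeneracyError):
        superpose(line, line + 1.0)


# ---------------------------------------------------------------------------
# interface RMSD


def test_interface_rmsd_native_zero(typed_complex):
    assert interface_rmsd(typed_complex, copy.deepcopy(typed_complex)) == (
        pytest.approx(0.0, abs=1e-9)
    )


def test_interface_rmsd_translation_closed_form(typed_complex):
    t = RigidTransform(axis=np.array([1.0, 0, 0]), angle_deg=0.0,
                       translation=np.array([0.0, 0.0, 2.0]))
    decoy = perturb_rigid(typed_complex, t)
    sel = extract_interface(typed_complex, cutoff=6.0)
    n_rna = sum(
        len(e.unit.heavy_atoms()) for e in sel.entries if e.molecule == "rna"
    )
    n_prot = sum(
        len(e.unit.heavy_atoms()) for e in sel.entries if e.molecule == "protein"
    )
    expected = np.sqrt(n_rna * 4.0 / (n_rna + n_prot))
    assert interface_rmsd(typed_complex, decoy) == pytest.approx(expected, abs=1e-9)


def test_interface_rmsd_rigid_motion_invariance(typed_complex):
    t = RigidTransform(axis=np.array([0.1, 0.9, 0.2]), angle_deg=20.0,
                       translation=np.array([1.0, 1.0, -2.0]))
    decoy = perturb_rigid(typed_complex, t)
    base = interface_rmsd(typed_complex, decoy)
    rng = np.random.default_rng(8)
    for _ in range(3):
        Q, tv = random_rigid(rng)
        moved = transform_complex(decoy, Q, tv)
        assert interface_rmsd(typed_complex, moved) == pytest.approx(base, abs=1e-6)


def test_interface_rmsd_empty_interface(typed_complex):
    far = copy.deepcopy(typed_complex)
    for unit in far.rna_units:
        for atom in unit.atoms:
            atom.position = atom.position + np.array([500.0, 0, 0])
    with pytest.raises(UndefinedMetricError):
        interface_rmsd(far, copy.deepcopy(far))


def test_interface_rmsd_pairing_error(typed_complex):
    decoy = copy.deepcopy(typed_complex)
    decoy.protein_units[0].atoms = decoy.protein_units[0].atoms[1:]
    with pytest.raises(PairingError):
        interface_rmsd(typed_complex, decoy)


def test_interface_rmsd_backbone_superposition_flag(typed_complex):
    t = RigidTransform(axis=np.array([1.0, 0, 0]), angle_deg=0.0,
                       translation=np.array([0.0, 1.0, 0.0]))
    decoy = perturb_rigid(typed_complex, t)
    heavy = interface_rmsd(typed_complex, decoy, superpose_atoms="heavy")
    backbone = interface_rmsd(typed_complex, decoy, superpose_atoms="backbone")
    # protein is unmoved, so both superpositions are identity-like
    assert heavy == pytest.approx(backbone, abs=1e-9)


# ---------------------------------------------------------------------------
# success rates


def _report(complex_id, irmsds):
    ranked = [
        RankedDecoy(decoy_id=f"d{i}", score=float(i), irmsd=r)
        for i, r in enumerate(irmsds)
    ]
    return ComplexReport(complex_id, ranked)


def test_success_native_rank1():
    reports = [_report(f"c{k}", [0.0, 9.0, 9.0]) for k in range(4)]
    assert success_rate(reports, 1) == 1.0


def test_success_boundary_exactly_4A():
    reports = [_report("c", [9.0, 9.0, 4.0, 9.0, 9.0])]
    assert success_rate(reports, 5) == 1.0
    assert success_rate(reports, 2) == 0.0


def test_success_rank6_constructed():
    irmsds = [9.0, 8.5, 8.0, 7.5, 7.0, 3.0, 9.0, 9.0, 9.0, 9.0]
    reports = [_report("c", irmsds)]
    assert success_rate(reports, 5) == 0.0
    assert success_rate(reports, 10) == 1.0


def test_success_monotone_in_n_and_threshold():
    rng = np.random.default_rng(9)
    reports = [
        _report(f"c{k}", list(rng.uniform(1.0, 12.0, size=20))) for k in range(6)
    ]
    rates_n = [success_rate(reports, n) for n in (1, 5, 10, 20)]
    assert rates_n == sorted(rates_n)
    rates_t = [success_rate(reports, 5, threshold=t) for t in (2.0, 4.0, 8.0)]
    assert rates_t == sorted(rates_t)


def test_success_empty_reports():
    with pytest.raises(EmptyInputError):
        success_rate([], 5)


def test_evaluation_report_dict():
    reports = [_report("c1", [0.5, 9.0]), _report("c2", [9.0, 9.0])]
    rep = EvaluationReport(reports=reports, top_n=(1, 2))
    assert rep.success == {1: 0.5, 2: 0.5}
    d = rep.to_dict()
    assert d["n_complexes"] == 2
    assert d["success_at_n"]["1"] == 0.5


# ---------------------------------------------------------------------------
# hydrogen bonds


def _hb_complex(dist, with_h=None, donor_name="N4", acceptor_name="O"):
    """C nucleotide donor vs backbone O acceptor at given separation."""
    rna_atoms = [
        AtomRecord("C1'", "C", np.array([0.0, -3.0, 0.0]), 0, "R"),
        AtomRecord(donor_name, donor_name[0], np.zeros(3), 0, "R"),
    ]
    if with_h is not None:
        rna_atoms.append(
            AtomRecord("H41", "H", np.asarray(with_h, float), 0, "R",
                       is_hydrogen=True)
        )
    prot_atoms = [
        AtomRecord("CA", "C", np.array([dist, 2.0, 0.0]), 1, "P"),
        AtomRecord(acceptor_name, "O", np.array([dist, 0.0, 0.0]), 1, "P"),
    ]
    return ComplexStructure(
        protein_units=[ResidueUnit("amino_acid", "ALA", prot_atoms, "P", 1)],
        rna_units=[ResidueUnit("nucleotide", "C", rna_atoms, "R", 1)],
    )


def test_hbond_reported_within_cutoffs():
    c = _hb_complex(3.30, with_h=(0.85, 0.0, 0.0))  # H-acceptor 2.45
    bonds = find_hbonds(c)
    assert len(bonds) == 1
    assert bonds[0].donor_acceptor_distance == pytest.approx(3.30)
    assert bonds[0].hydrogen_acceptor_distance == pytest.approx(2.45)


def test_hbond_rejected_beyond_da_cutoff():
    assert find_hbonds(_hb_complex(3.40)) == []


def test_hbond_rejected_beyond_h_cutoff():
    c = _hb_complex(3.30, with_h=(-0.9, 0.0, 0.0))  # H-acceptor 4.2
    assert find_hbonds(c) == []


def test_hbond_heavy_only_without_hydrogens():
    bonds = find_hbonds(_hb_complex(3.30))
    assert len(bonds) == 1
    assert bonds[0].hydrogen_acceptor_distance is None


def test_hbond_invariant_enforced():
    with pytest.raises(ValueError):
        HydrogenBond(
            donor=("rna", "R", 1, "N4"),
            acceptor=("protein", "P", 1, "O"),
            donor_acceptor_distance=3.5,
            hydrogen_acceptor_distance=None,
        )


def test_hbond_count_matches_bruteforce(typed_complex):
    from rnpscore.evaluate import (
        HBOND_DONOR_ACCEPTOR_MAX,
        _PROTEIN_ACCEPTORS,
        _PROTEIN_DONORS,
        _RNA_ACCEPTORS,
        _RNA_DONORS,
        _in_class,
    )

    bonds = find_hbonds(typed_complex)
    count = 0  # no hydrogens in the toy complex: heavy criterion alone
    for ru in typed_complex.rna_units:
        for pu in typed_complex.protein_units:
            for ra in ru.heavy_atoms():
                for pa in pu.heavy_atoms():
                    d = float(np.linalg.norm(ra.position - pa.position))
                    if d > HBOND_DONOR_ACCEPTOR_MAX:
                        continue
                    if _in_class(_RNA_DONORS, ru.type_code, ra.name) and _in_class(
                        _PROTEIN_ACCEPTORS, pu.type_code, pa.name
                    ):
                        count += 1
                    if _in_class(_PROTEIN_DONORS, pu.type_code, pa.name) and _in_class(
                        _RNA_ACCEPTORS, ru.type_code, ra.name
                    ):
                        count += 1
    assert len(bonds) == count
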