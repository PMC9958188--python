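import numpy as np
import pytest

from rnpscore.decoygen import generate_toy_complex, write_pdb
from rnpscore.errors import CompositionError, ParseError, TypingError
from rnpscore.structures import (
    AtomRecord,
    AtomTypeTable,
    ComplexStructure,
    ResidueUnit,
    assign_types,
    count_types,
    extract_interface,
    parse_pdb,
)

# ---------------------------------------------------------------------------
# parsing


def test_parse_toy_roundtrip(tmp_path):
    complex_ = generate_toy_complex(seed=1, n_nt=4, n_aa=5)
    path = tmp_path / "toy.pdb"
    write_pdb(complex_, path)
    parsed = parse_pdb(path)
    assert len(parsed.rna_units) == 4
    assert len(parsed.protein_units) == 5


def test_parse_protein_only_raises(tmp_path):
    lines = []
    for i, (name, x) in enumerate(
        [("N", 0.0), ("CA", 1.5), ("C", 2.9), ("O", 3.5), ("CB", 1.6)], start=1
    ):
        lines.append(
            f"ATOM  {i:5d}  {name:<3s} ALA A   1    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           {name[0]}"
        )
    (tmp_path / "prot.pdb").write_text("\n".join(lines) + "\nEND\n")
    with pytest.raises(CompositionError):
        parse_pdb(tmp_path / "prot.pdb")


def test_parse_unreadable_path():
    with pytest.raises((ParseError, FileNotFoundError)):
        parse_pdb("/nonexistent/file.pdb")


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    # CA given on two altloc lines with occupancies 0.6 / 0.4; the parser
    # must keep the 0.6 position (x = 1.5), verified against a manual read
    # of the fixture text below.
    pdb = "\n".join(
        [
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA AALA A   1       1.500   0.000   0.000  0.60  0.00           C",
            "ATOM      3  CA BALA A   1       9.900   0.000   0.000  0.40  0.00           C",
            "ATOM      4  C   ALA A   1       2.900   0.500   0.000  1.00  0.00           C",
            "ATOM      5  O   ALA A   1       3.500   1.500   0.000  1.00  0.00           O",
            "ATOM      6  P     A R   1       0.000   5.000   0.000  1.00  0.00           P",
            "ATOM      7  C1'   A R   1       1.000   5.000   0.000  1.00  0.00           C",
            "END",
        ]
    )
    path = tmp_path / "altloc.pdb"
    path.write_text(pdb + "\n")
    parsed = parse_pdb(path)
    ca = parsed.protein_units[0].atom("CA")
    assert ca is not None
    assert ca.position[0] == pytest.approx(1.5)
    assert parsed.protein_units[0].atom("CA") is not None
    assert len([a for a in parsed.protein_units[0].atoms if a.name == "CA"]) == 1


def test_units_sorted_by_chain_and_seq():
    def unit(chain, seq):
        atoms = [AtomRecord("CA", "C", np.zeros(3), 0, chain)]
        return ResidueUnit("amino_acid", "GLY", atoms, chain, seq)

    rna_atoms = [AtomRecord("C1'", "C", np.ones(3), 0, "R")]
    rna = ResidueUnit("nucleotide", "A", rna_atoms, "R", 1)
    c = ComplexStructure(
        protein_units=[unit("B", 2), unit("A", 9), unit("B", 1)],
        rna_units=[rna],
    )
    assert [u.key for u in c.protein_units] == [("A", 9), ("B", 1), ("B", 2)]


# ---------------------------------------------------------------------------
# typing tables


def test_rna_table_count_is_85(canonical_rna_table):
    assert count_types(canonical_rna_table) == 85


def test_protein_table_count_is_167(canonical_protein_table):
    # independent enumeration over standard amino-acid heavy atoms
    from rnpscore import chemdata

    expected = sum(
        4 + len(chemdata.PROTEIN_SIDECHAIN_ATOMS[code])
        for code in chemdata.AMINO_CODES
    )
    assert expected == 167
    assert count_types(canonical_protein_table) == expected


def test_empty_table_count():
    assert count_types(AtomTypeTable(entries={}, molecule="rna")) == 0


def test_table_masses_positive(canonical_rna_table, canonical_protein_table):
    for table in (canonical_rna_table, canonical_protein_table):
        assert all(mass > 0 for _, mass, _ in table.entries.values())


def test_table_type_ids_contiguous(canonical_rna_table):
    ids = sorted(tid for tid, _, _ in canonical_rna_table.entries.values())
    assert ids == list(range(85))


def test_table_tsv_roundtrip(tmp_path, canonical_rna_table):
    path = tmp_path / "rna.tsv"
    canonical_rna_table.to_tsv(path)
    reloaded = AtomTypeTable.from_tsv(path, "rna")
    assert reloaded.entries == canonical_rna_table.entries


# ---------------------------------------------------------------------------
# type assignment


def test_assign_types_adenosine_c1(typed_complex, tables):
    rna_table, _ = tables
    unit = next(u for u in typed_complex.rna_units if u.type_code == "A")
    atom = unit.atom("C1'")
    tid, mass, charge = rna_table.lookup("A", "C1'")
    assert (atom.type_id, atom.mass, atom.charge) == (tid, mass, charge)


def test_assign_types_skip_drops_unknown(toy_complex, tables):
    rna_table, protein_table = tables
    bad = AtomRecord("XX1", "C", np.array([99.0, 99.0, 99.0]), 0, "R")
    toy_complex.rna_units[0].atoms.append(bad)
    n_before = sum(
        len(u.heavy_atoms()) for _, u in toy_complex.iter_units()
    )
    assign_types(toy_complex, rna_table, protein_table, unknown_policy="skip")
    n_typed = len(toy_complex.typed_heavy_atoms())
    assert n_typed == n_before - 1


def test_assign_types_fail_raises(toy_complex, tables):
    rna_table, protein_table = tables
    bad = AtomRecord("XX1", "C", np.array([99.0, 99.0, 99.0]), 0, "R")
    toy_complex.rna_units[0].atoms.append(bad)
    with pytest.raises(TypingError, match="XX1"):
        assign_types(toy_complex, rna_table, protein_table, unknown_policy="fail")


def test_assign_types_count_matches_membership_scan(toy_complex, tables):
    rna_table, protein_table = tables
    # independent brute-force membership count before annotation
    expected = 0
    for unit in toy_complex.rna_units:
        expected += sum(
            1 for a in unit.heavy_atoms()
            if (unit.type_code, a.name) in rna_table.entries
        )
    for unit in toy_complex.protein_units:
        expected += sum(
            1 for a in unit.heavy_atoms()
            if (unit.type_code, a.name) in protein_table.entries
        )
    assign_types(toy_complex, rna_table, protein_table)
    assert len(toy_complex.typed_heavy_atoms()) == expected


# ---------------------------------------------------------------------------
# interface extraction


def _two_atom_complex(separation):
    rna_atom = AtomRecord("C1'", "C", np.zeros(3), 0, "R")
    prot_atom = AtomRecord("CA", "C", np.array([separation, 0.0, 0.0]), 1, "P")
    return ComplexStructure(
        protein_units=[ResidueUnit("amino_acid", "GLY", [prot_atom], "P", 1)],
        rna_units=[ResidueUnit("nucleotide", "A", [rna_atom], "R", 1)],
    )


def test_interface_within_cutoff():
    sel = extract_interface(_two_atom_complex(5.9), cutoff=6.0)
    assert len(sel) == 2


def test_interface_boundary_closed():
    sel = extract_interface(_two_atom_complex(6.0), cutoff=6.0)
    assert len(sel) == 2


def test_interface_far_apart_empty():
    sel = extract_interface(_two_atom_complex(100.0), cutoff=6.0)
    assert sel.is_empty


def test_interface_matches_bruteforce(typed_complex):
    sel = extract_interface(typed_complex, cutoff=6.0)
    selected = {(e.molecule, e.unit.key) for e in sel.entries}
    # O(n^2) double loop over all heavy-atom pairs
    rna_coords = {
        u.key: u.heavy_coords() for u in typed_complex.rna_units
    }
    prot_coords = {
        u.key: u.heavy_coords() for u in typed_complex.protein_units
    }
    expected = set()
    for rk, rc in rna_coords.items():
        for pk, pc in prot_coords.items():
            dmin = min(
                float(np.linalg.norm(ra - pa)) for ra in rc for pa in pc
            )
            if dmin <= 6.0:
                expected.add(("rna", rk))
                expected.add(("protein", pk))
    assert selected == expected


def test_interface_min_distances_match_bruteforce(typed_complex):
    sel = extract_interface(typed_complex, cutoff=6.0)
    prot = typed_complex.heavy_coords("protein")
    rna = typed_complex.heavy_coords("rna")
    partner = {"rna": prot, "protein": rna}
    for e in sel.entries:
        coords = e.unit.heavy_coords()
        dmin = min(
            float(np.linalg.norm(a - b))
            for a in coords
            for b in partner[e.molecule]
        )
        assert e.min_partner_distance == pytest.approx(dmin, abs=1e-9)


def test_interface_monotone_in_cutoff(typed_complex):
    keys = {}
    for cutoff in (4.0, 6.0, 9.0):
        sel = extract_interface(typed_complex, cutoff=cutoff)
        keys[cutoff] = {(e.molecule, e.unit.key) for e in sel.entries}
    assert keys[4.0] <= keys[6.0] <= keys[9.0]


def test_interface_ordering_rna_first(typed_complex):
    sel = extract_interface(typed_complex, cutoff=6.0)
    molecules = [e.molecule for e in sel.entries]
    assert molecules == sorted(molecules, key=lambda m: m != "rna")
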