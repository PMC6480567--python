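"""Molecular data model: geometry generation, PDB round-trips, protonation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irdl import residues as rt
from irdl.geometry import dihedral
from irdl.structures import (EmptySystemError, MolecularSystem, PeptideModel,
                             UnsupportedResidueError, assign_protonation,
                             build_peptide, count_rotatable_bonds,
                             net_formal_charge, read_pdb, write_pdb)

LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.mark.parametrize("aa", sorted(LETTERS))
def test_residue_geometry_is_chemically_sane(aa):
    """Every declared bond of every residue type has a covalent length."""
    model = PeptideModel(aa * 3)
    x = model.coords()
    for i, j in model.bonds:
        d = np.linalg.norm(x[i] - x[j])
        assert 1.1 < d < 2.2, (model.atom_names[i], model.atom_names[j], d)


def test_backbone_torsions_round_trip():
    model = PeptideModel("AAAA")
    values = model.default_torsions()
    values[model.torsion_index("phi", 1)] = -63.0
    values[model.torsion_index("psi", 1)] = -42.0
    x = model.coords(values)
    i = model.atom_index
    phi = dihedral(x[i(0, "C")], x[i(1, "N")], x[i(1, "CA")], x[i(1, "C")])
    psi = dihedral(x[i(1, "N")], x[i(1, "CA")], x[i(1, "C")], x[i(2, "N")])
    omega = dihedral(x[i(0, "CA")], x[i(0, "C")], x[i(1, "N")],
                     x[i(1, "CA")])
    assert phi == pytest.approx(-63.0, abs=1e-6)
    assert psi == pytest.approx(-42.0, abs=1e-6)
    assert abs(omega) == pytest.approx(180.0, abs=1e-6)


def test_chirality_is_l_amino_acid():
    model = PeptideModel("A")
    x = model.coords()
    i = model.atom_index
    triple = np.dot(np.cross(x[i(0, "N")] - x[i(0, "CA")],
                             x[i(0, "C")] - x[i(0, "CA")]),
                    x[i(0, "CB")] - x[i(0, "CA")])
    assert triple > 0


def test_pdb_round_trip_preserves_structure(tmp_path):
    system = build_peptide("GWKDF")
    path = tmp_path / "pep.pdb"
    write_pdb(system, path)
    back = read_pdb(path, chain_policy="keep-all", role="peptide")
    assert back.n_atoms == system.n_atoms
    assert [a.name for a in back.atoms()] == [a.name for a in system.atoms()]
    assert np.abs(back.coords() - system.coords()).max() <= 1e-3
    assert len({r.seq_index for r in back.residues()}) == 5


def test_read_pdb_policies(tmp_path):
    """first-monomer keeps one chain; waters are always dropped."""
    from irdl.structures import Chain
    a = build_peptide("AG")
    b = build_peptide("KD")
    b.chains[0].label = "B"
    both = MolecularSystem([a.chains[0], b.chains[0]], role="receptor")
    path = tmp_path / "two.pdb"
    write_pdb(both, path)
    with open(path) as fh:
        text = fh.read()
    text = text.replace("END", "") + (
        "HETATM 9001  O   HOH A 900      10.000  10.000  10.000"
        "  1.00  0.00           O\nEND\n")
    path2 = tmp_path / "two_hoh.pdb"
    path2.write_text(text)
    mono = read_pdb(path2, chain_policy="first-monomer")
    assert len(mono.chains) == 1
    full = read_pdb(path2, chain_policy="keep-all")
    assert len(full.chains) == 2
    assert all(r.name != "HOH" for r in full.residues())


def test_write_empty_system_fails(tmp_path):
    with pytest.raises(EmptySystemError):
        write_pdb(MolecularSystem([], role="peptide"), tmp_path / "e.pdb")


def test_malformed_pdb_names_line(tmp_path):
    from irdl.structures import PDBParseError
    path = tmp_path / "bad.pdb"
    path.write_text("ATOM      1  N   ALA A   1      xx.xxx   0.000"
                    "   0.000  1.00  0.00           N\n")
    with pytest.raises(PDBParseError) as err:
        read_pdb(path)
    assert err.value.lineno == 1


@pytest.mark.parametrize("seq,expected", [
    ("G", 1),           # carboxyl only
    ("AAAAA", 9),       # 4 phi + 4 psi + 0 chi + 1
    ("A" * 12, 23),
    ("K", 5),           # 4 chi + carboxyl
    ("PP", 2),          # no phi, no chi for Pro: 1 psi + carboxyl
])
def test_rotatable_bond_counts(seq, expected):
    assert count_rotatable_bonds(seq) == expected


def test_rotatable_bonds_appending_ala_adds_two():
    for seq in ("G", "KWD", "PPG"):
        assert count_rotatable_bonds(seq + "A") == \
            count_rotatable_bonds(seq) + 2


def test_rotatable_bonds_rejects_nonstandard():
    with pytest.raises(UnsupportedResidueError):
        count_rotatable_bonds("AXZ")


@pytest.mark.parametrize("seq,charge", [
    ("DKDK", 0),        # 2(-1) + 2(+1) + termini (+1 -1)
    ("AAAA", 0),        # termini only
    ("KKRR", 4),
    ("DDEE", -4),
])
def test_protonation_net_charge(seq, charge):
    system = assign_protonation(build_peptide(seq), pH=7.4)
    assert net_formal_charge(system) == charge


def test_protonation_rule_table():
    system = assign_protonation(build_peptide("KDHA"), pH=7.4)
    residues = list(system.residues())
    assert residues[0].formal_charge == 2    # Lys sidechain + N-terminus
    assert residues[1].formal_charge == -1   # Asp
    assert residues[2].formal_charge == 0    # His neutral at 7.4
    assert residues[3].formal_charge == -1   # free C-terminus


def test_protonation_rejects_bad_ph():
    with pytest.raises(ValueError):
        assign_protonation(build_peptide("AA"), pH=15.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.text(alphabet="AGSKDFW", min_size=1, max_size=8),
       st.text(alphabet="AGSKDFW", min_size=1, max_size=8))
def test_rotatable_bond_additivity(seq1, seq2):
    """count(a+b) = count(a) + count(b) + 1 (the joined peptide gains one
    phi and one psi at the junction but loses one carboxyl rotation)."""
    assert count_rotatable_bonds(seq1 + seq2) == \
        count_rotatable_bonds(seq1) + count_rotatable_bonds(seq2) + 1
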