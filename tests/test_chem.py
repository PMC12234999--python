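"""Molecule/reaction parsing, featurization and count statistics."""

import numpy as np
import pytest
from rdkit import Chem

from csglearn.chem import (
    AtomFeaturizer,
    MoleculeParseError,
    ReactionParseError,
    atom_feature_vector,
    count_bond_types,
    count_bonds,
    count_rings,
    default_bond_type_vocabulary,
    parse_molecule,
    parse_reaction,
    read_reaction_file,
    write_reaction_file,
)
from csglearn.synth import generate_molecules


@pytest.mark.parametrize(
    "smiles,n_atoms,n_bonds,n_rings",
    [
        ("O", 1, 0, 0),
        ("CCO", 3, 2, 0),
        ("c1ccccc1", 6, 6, 1),
        ("c1ccc2ccccc2c1", 10, 11, 2),
        ("CC(=O)O", 4, 3, 0),
    ],
)
def test_parse_molecule_counts(smiles, n_atoms, n_bonds, n_rings):
    mol = parse_molecule(smiles)
    assert mol.num_atoms == n_atoms
    assert mol.num_bonds == n_bonds
    assert mol.ring_count == n_rings


def test_parse_molecule_rejects_garbage():
    with pytest.raises(MoleculeParseError, match="not-a-smiles"):
        parse_molecule("not-a-smiles")


def test_canonical_id_idempotent():
    for mol in generate_molecules(40, seed=7):
        assert parse_molecule(mol.canonical_id).canonical_id == mol.canonical_id


def test_bond_indices_valid_and_no_self_bonds():
    for mol in generate_molecules(30, seed=3):
        for i, j, _ in mol.bonds:
            assert i != j
            assert 0 <= i < mol.num_atoms and 0 <= j < mol.num_atoms


def test_parse_reaction_basic():
    rxn = parse_reaction("CC(=O)O.OCC>>CC(=O)OCC.O")
    assert len(rxn.reactants) == 2 and len(rxn.products) == 2
    identity = parse_reaction("CCO>>CCO")
    assert identity.reactants[0].canonical_id == identity.products[0].canonical_id


def test_parse_reaction_discards_agents():
    rxn = parse_reaction("CCO>[Na]>CCO")
    assert len(rxn.reactants) == 1 and len(rxn.products) == 1


@pytest.mark.parametrize("bad", ["CCO>>", ">>CCO", "CCO", "CCO>>xx$yy"])
def test_parse_reaction_errors(bad):
    with pytest.raises(ReactionParseError):
        parse_reaction(bad)


def test_counts_match_rdkit_enumeration(vocab):
    """Dual route: counts from the package's bond/ring lists vs direct RDKit."""
    for mol in generate_molecules(200, seed=11):
        rd = Chem.MolFromSmiles(mol.canonical_id)
        assert count_bonds([mol]) == rd.GetNumBonds()
        assert count_rings([mol]) == len(Chem.GetSSSR(rd))
        per_type = count_bond_types([mol], vocab)
        assert per_type.sum() <= mol.num_bonds
        assert (per_type >= 0).all()


def test_count_examples(vocab):
    pair = [parse_molecule("CC(=O)O"), parse_molecule("OCC")]
    assert count_bonds(pair) == 5
    diels = [parse_molecule("C=CC=C"), parse_molecule("C=C")]
    assert count_bonds(diels) == 4
    assert count_rings([parse_molecule("c1ccccc1")]) == 1
    counts = count_bond_types([parse_molecule("CCO")], vocab)
    assert counts[vocab.index_of("C", "C", "SINGLE")] == 1
    assert counts[vocab.index_of("C", "O", "SINGLE")] == 1
    assert counts.sum() == 2


def test_counts_additive_over_multiset_union(vocab):
    mols = generate_molecules(10, seed=5)
    a, b = mols[:4], mols[4:]
    assert count_bonds(a) + count_bonds(b) == count_bonds(a + b)
    assert count_rings(a) + count_rings(b) == count_rings(a + b)
    np.testing.assert_array_equal(
        count_bond_types(a, vocab) + count_bond_types(b, vocab),
        count_bond_types(a + b, vocab),
    )
    # multiplicity counts: a duplicated molecule counts twice
    assert count_bonds([mols[0], mols[0]]) == 2 * mols[0].num_bonds


def test_atom_feature_vector_contract():
    mols = generate_molecules(25, seed=2)
    feat = AtomFeaturizer.from_molecules(mols)
    for mol in mols[:10]:
        for atom in mol.atoms:
            vec = atom_feature_vector(atom, feat)
            assert vec.sum() == 4.0  # one per one-hot block
            assert vec.shape == (feat.feature_dim,)
    a0 = mols[0].atoms[0]
    np.testing.assert_array_equal(
        atom_feature_vector(a0, feat), atom_feature_vector(a0, feat)
    )


def test_unknown_element_falls_into_unk_bucket():
    feat = AtomFeaturizer(["C", "O"])
    selenium = parse_molecule("[SeH2]").atoms[0]
    vec = feat.atom_vector(selenium)
    assert vec.sum() == 4.0
    assert vec[len(feat.CHARGES) + len(feat.elements)] == 1.0


def test_reaction_file_round_trip(tmp_path):
    lines = ["CC(=O)O.OCC>>CC(=O)OCC.O\t1", "# comment", "C=CC=C.C=C>>C1CCC=CC1\t2"]
    path = tmp_path / "rxn.tsv"
    path.write_text("\n".join(lines) + "\n")
    rxns = read_reaction_file(path)
    assert [r.class_label for r in rxns] == [1, 2]
    out = tmp_path / "round.tsv"
    write_reaction_file(out, rxns)
    again = read_reaction_file(out)
    assert [r.smiles for r in again] == [r.smiles for r in rxns]


def test_bond_vocab_default_and_io(tmp_path, vocab):
    assert vocab.size == 15
    assert vocab.index_of("O", "C", "SINGLE") == vocab.index_of("C", "O", "SINGLE")
    assert vocab.index_of("C", "Cl", "SINGLE") is None  # OTHER bucket
    for name in ("vocab.yaml", "vocab.json"):
        p = tmp_path / name
        vocab.save(p)
        loaded = type(vocab).load(p)
        assert [e.key() for e in loaded.entries] == [e.key() for e in vocab.entries]
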