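"""Molecule encoder: architectures, pooling, invariances, gradient flow."""

import numpy as np
import pytest
from rdkit import Chem

from csglearn.autodiff import Tensor, finite_difference_grad
from csglearn.chem import AtomFeaturizer, parse_molecule
from csglearn.encoder import (
    BatchedGraph,
    EncoderConfig,
    MoleculeEncoder,
    encode_atoms,
    encode_molecule,
    pool,
)
from csglearn.synth import generate_molecules

MOLS = generate_molecules(30, seed=21)
FEAT = AtomFeaturizer.from_molecules(MOLS)


def _encoder(gnn="gcn", pooling="sum", dim=8, seed=0):
    cfg = EncoderConfig(gnn_type=gnn, pooling=pooling, hidden_dim=dim, num_layers=2)
    return MoleculeEncoder(cfg, FEAT, np.random.default_rng(seed))


def _renumbered(smiles: str, rng) -> str:
    mol = Chem.MolFromSmiles(smiles)
    perm = rng.permutation(mol.GetNumAtoms()).tolist()
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, [int(i) for i in perm]), canonical=False)


def test_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(gnn_type="transformer").validate()
    with pytest.raises(ValueError):
        EncoderConfig(pooling="mean-of-means").validate()


@pytest.mark.parametrize("gnn", ["gcn", "gat", "sage", "tag"])
def test_deterministic_and_right_shape(gnn):
    enc = _encoder(gnn=gnn)
    out1 = enc.encode_molecules(MOLS[:5])
    out2 = enc.encode_molecules(MOLS[:5])
    assert out1.shape == (5, 8)
    np.testing.assert_array_equal(out1, out2)


def test_single_atom_molecule_all_architectures():
    water = parse_molecule("O")
    for gnn in ("gcn", "gat", "sage", "tag"):
        emb = encode_molecule(water, _encoder(gnn=gnn))
        assert emb.shape == (8,)
        assert np.all(np.isfinite(emb))


def test_sum_pool_of_single_atom_equals_final_layer():
    water = parse_molecule("O")
    enc = _encoder()
    layers = encode_atoms(water, enc)
    assert layers[0].shape[0] == 1
    np.testing.assert_allclose(encode_molecule(water, enc), layers[-1][0])


@pytest.mark.parametrize("gnn", ["gcn", "gat", "sage", "tag"])
@pytest.mark.parametrize("pooling", ["sum", "avg", "max", "attention", "set2set"])
def test_permutation_invariance(gnn, pooling, rng):
    """Relabeling atoms must not change permutation-invariant embeddings."""
    enc = _encoder(gnn=gnn, pooling=pooling)
    for mol in MOLS[:6]:
        base = encode_molecule(mol, enc)
        perm_smiles = _renumbered(mol.canonical_id, rng)
        mol_perm = parse_molecule(perm_smiles)
        assert mol_perm.canonical_id == mol.canonical_id
        # encode through the permuted atom ordering without re-canonicalizing
        from rdkit import Chem as _C

        rd = _C.MolFromSmiles(perm_smiles, sanitize=True)
        from csglearn.chem import Atom, Molecule

        atoms = tuple(
            Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs(), a.IsInRing())
            for a in rd.GetAtoms()
        )
        bonds = tuple(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondType().name)
            for b in rd.GetBonds()
        )
        permuted = Molecule(mol.canonical_id, atoms, bonds, mol.ring_count)
        other = encode_molecule(permuted, enc)
        np.testing.assert_allclose(base, other, atol=1e-5)


def test_atom_embedding_rows_permute_with_atoms(rng):
    """Message passing is equivariant: relabeled atoms permute output rows."""
    enc = _encoder(gnn="gcn")
    mol = MOLS[3]
    base = encode_atoms(mol, enc)[-1]
    rd = Chem.MolFromSmiles(mol.canonical_id)
    perm = [int(i) for i in rng.permutation(rd.GetNumAtoms())]
    rd2 = Chem.RenumberAtoms(rd, perm)
    from csglearn.chem import Atom, Molecule

    atoms = tuple(
        Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs(), a.IsInRing())
        for a in rd2.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondType().name)
        for b in rd2.GetBonds()
    )
    permuted = Molecule(mol.canonical_id, atoms, bonds, mol.ring_count)
    out = encode_atoms(permuted, enc)[-1]
    np.testing.assert_allclose(out, base[perm], atol=1e-8)


def test_pool_examples():
    enc = _encoder()
    mol = MOLS[0]
    final = encode_atoms(mol, enc)[-1]
    summed = pool(final, "sum", enc, mol)
    np.testing.assert_allclose(summed, final.sum(axis=0))
    identical = np.tile(final[:1], (mol.num_atoms, 1))
    np.testing.assert_allclose(pool(identical, "avg", enc, mol), final[0])
    with pytest.raises(ValueError):
        pool(final, "median", enc, mol)


def test_sortpool_runs_and_projects():
    enc = _encoder(pooling="sortpool")
    out = enc.encode_molecules(MOLS[:4])
    assert out.shape == (4, 8)
    assert np.all(np.isfinite(out))


@pytest.mark.parametrize("gnn", ["gcn", "gat", "sage", "tag"])
def test_gradient_flow_finite_difference(gnn):
    """Autodiff gradients through encoder + pooling match finite differences."""
    enc = _encoder(gnn=gnn, dim=4)
    batch = BatchedGraph(MOLS[:3], FEAT)

    def loss():
        emb = enc.encode_batch(batch)
        return (emb * emb).sum()

    name = "enc.l0.W" if gnn in ("gcn", "gat") else ("enc.l0.W_self" if gnn == "sage" else "enc.l0.W0")
    param = enc.params[name]
    value = loss()
    value.backward()
    ad = param.grad.copy()
    fd = finite_difference_grad(loss, param)
    denom = max(np.abs(fd).max(), 1e-8)
    assert np.abs(ad - fd).max() / denom < 1e-4


def test_checkpoint_param_shape_mismatch_fails():
    enc = _encoder()
    bad = {k: v.data for k, v in enc.params.items()}
    bad["enc.l0.W"] = np.zeros((2, 2))
    with pytest.raises(ValueError, match="shape mismatch"):
        enc.load_params(bad)
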