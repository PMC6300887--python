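import numpy as np
import pytest
from rdkit import Chem

from neuralfp import neural_fingerprint as nf
from neuralfp.chem_io import (
    AtomRecord,
    BondRecord,
    MoleculeGraph,
    N_BOND_FEATURES,
    atom_features,
    bond_features,
    parse_molecule,
)


def reordered_alias(smiles: str, rng) -> str:
    """A SMILES of the same molecule written from a random atom order."""
    mol = Chem.MolFromSmiles(smiles)
    perm = rng.permutation(mol.GetNumAtoms())
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, [int(i) for i in perm]), canonical=False)


class TestInitParams:
    def test_reference_configuration_shapes(self):
        p = nf.init_params(R=4, K=50, seed=0)
        assert len(p.H) == 4 and all(set(layer) == {1, 2, 3, 4, 5} for layer in p.H)
        assert len(p.F) == 5
        d1 = p.encoding.n_features
        for deg in range(1, 6):
            assert p.H[0][deg].shape == (d1 + deg * (d1 + N_BOND_FEATURES), d1)
        assert all(F.shape == (d1, 50) for F in p.F)

    def test_same_seed_identical_weights(self):
        a, b = nf.init_params(3, 16, seed=11), nf.init_params(3, 16, seed=11)
        for k in a.keys():
            assert np.array_equal(a.get(k), b.get(k))

    def test_minimal_network(self):
        p = nf.init_params(R=1, K=2, seed=0)
        assert len(p.H) == 1 and len(p.F) == 2

    @pytest.mark.parametrize("R,K", [(0, 5), (2, 0)])
    def test_nonpositive_dims_rejected(self, R, K):
        with pytest.raises(nf.FingerprintError):
            nf.init_params(R, K)

    def test_checkpoint_roundtrip(self, tmp_path):
        p = nf.init_params(2, 8, seed=3)
        p.save(tmp_path / "fp.ckpt")
        q = nf.FingerprintParams.load(tmp_path / "fp.ckpt")
        assert q.R == p.R and q.K == p.K and q.write_levels == p.write_levels
        for k in p.keys():
            assert np.array_equal(p.get(k), q.get(k))
        mol = parse_molecule("CCO")
        assert np.array_equal(nf.fingerprint(mol, p).z, nf.fingerprint(mol, q).z)


class TestNeighborConcat:
    def test_shape_arithmetic(self):
        mol = parse_molecule("CC")
        X = atom_features(mol).values
        d = X.shape[1]
        assert nf.neighbor_concat(X, mol, 0).shape == (d + (d + 6),)

    def test_isolated_atom_self_only(self):
        mol = parse_molecule("C")
        X = atom_features(mol).values
        assert np.array_equal(nf.neighbor_concat(X, mol, 0), X[0])

    def test_benzene_symmetric(self):
        mol = parse_molecule("c1ccccc1")
        X = atom_features(mol).values
        d = X.shape[1]
        vecs = [nf.neighbor_concat(X, mol, j) for j in range(6)]
        assert all(v.shape == (d + 2 * (d + 6),) for v in vecs)
        assert all(np.array_equal(v, vecs[0]) for v in vecs)


class TestLayerUpdate:
    def test_benzene_rows_identical_every_layer(self):
        mol = parse_molecule("c1ccccc1")
        p = nf.init_params(3, 8, seed=5)
        packed = nf.PackedGraphs.pack([nf.featurize_molecule(mol)])
        _, cache = nf.forward(packed, p)
        for X in cache.X:
            assert np.allclose(X, X[0], atol=1e-12)

    def test_zero_weights_zero_output(self):
        mol = parse_molecule("CCO")
        p = nf.init_params(1, 4, seed=0)
        for deg in p.H[0]:
            p.H[0][deg][:] = 0.0
        X1 = nf.layer_update(atom_features(mol).values, mol, p, 0)
        assert np.all(X1 == 0)  # tanh(0) = 0

    def test_matches_dense_matrix_oracle(self):
        # independent oracle: explicit per-atom concatenation + matmul
        mol = parse_molecule("CCO")
        p = nf.init_params(2, 6, seed=9)
        X0 = atom_features(mol).values
        B = bond_features(mol)
        expect = []
        for j in range(mol.n_atoms):
            v = [X0[j]]
            for n, bi in mol.neighbors(j):
                v.append(X0[n])
                v.append(B[bi])
            v = np.concatenate(v)
            expect.append(np.tanh(v @ p.H[0][len(mol.neighbors(j))] + p.b[0]))
        expect = np.vstack(expect)
        packed = nf.PackedGraphs.pack([nf.featurize_molecule(mol)])
        _, cache = nf.forward(packed, p)
        assert np.allclose(cache.X[1], expect, atol=1e-12)
        assert np.allclose(nf.layer_update(X0, mol, p, 0), expect, atol=1e-12)


class TestWriteContribution:
    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(7, 5))
        F = rng.normal(size=(5, 13))
        C = nf.write_contribution(X, F)
        assert np.allclose(C.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_weights_uniform(self):
        C = nf.write_contribution(np.ones((3, 4)), np.zeros((4, 10)))
        assert np.allclose(C, 0.1, atol=1e-15)

    def test_closed_form_two_bits(self):
        # logits (ln 3, 0) -> softmax (0.75, 0.25)
        X = np.array([[1.0]])
        F = np.array([[np.log(3.0), 0.0]])
        assert np.allclose(nf.write_contribution(X, F), [[0.75, 0.25]], atol=1e-12)


class TestFingerprint:
    def test_mass_conservation_forced_by_softmax(self):
        mol = parse_molecule("CC")
        p = nf.init_params(4, 50, seed=2)
        assert np.isclose(nf.fingerprint(mol, p).z.sum(), 2 * 5, atol=1e-9)

    def test_mass_conservation_random_molecules(self, corpus, rng):
        mols, _, _ = corpus
        for draw in range(3):
            R = int(rng.integers(1, 5))
            p = nf.init_params(R, int(rng.integers(4, 32)), seed=int(rng.integers(1000)))
            for i in rng.integers(0, len(mols), size=10):
                z = nf.fingerprint(mols[i], p).z
                assert abs(z.sum() - mols[i].n_atoms * (R + 1)) < 1e-9
                assert np.all(z >= 0)

    def test_permutation_invariance(self, rng):
        p = nf.init_params(3, 16, seed=4)
        for smiles in ["CCO", "c1ccncc1CCl", "CC(=O)NC1CCCCC1"]:
            z0 = nf.fingerprint(parse_molecule(smiles), p).z
            for _ in range(3):
                alias = reordered_alias(smiles, rng)
                z1 = nf.fingerprint(parse_molecule(alias), p).z
                assert np.abs(z0 - z1).max() < 1e-10

    def test_determinism(self):
        mol = parse_molecule("CCO")
        z0 = nf.fingerprint(mol, nf.init_params(2, 8, seed=6)).z
        z1 = nf.fingerprint(mol, nf.init_params(2, 8, seed=6)).z
        assert np.array_equal(z0, z1)

    def test_write_levels_configurable(self):
        mol = parse_molecule("CCO")
        p = nf.init_params(2, 8, seed=6, write_levels=(1, 2))
        assert np.isclose(nf.fingerprint(mol, p).z.sum(), 3 * 2, atol=1e-9)


def _chain_graph(elements: list[str]) -> MoleculeGraph:
    """Hand-built linear chain with fixed atom order (no canonicalization)."""
    valence = {"C": 4, "O": 2, "N": 3}
    atoms = []
    n = len(elements)
    for j, el in enumerate(elements):
        deg = int(j > 0) + int(j < n - 1)
        nh = valence[el] - deg
        atoms.append(AtomRecord(element=el, degree=deg, n_h=nh, implicit_valence=nh, is_aromatic=False))
    bonds = [BondRecord(j, j + 1, "single", False, False) for j in range(n - 1)]
    return MoleculeGraph(mol_id="".join(elements), atoms=atoms, bonds=bonds)


class TestRadiusLocality:
    def test_far_change_leaves_local_writes_unchanged(self):
        # chains identical except the last atom; per-level writes of atom j
        # depend only on atoms within distance <= level <= R of j
        R = 2
        p = nf.init_params(R, 12, seed=8)
        a = _chain_graph(["C"] * 9)
        b = _chain_graph(["C"] * 8 + ["O"])
        _, act_a = nf.fingerprint(a, p, return_activations=True)
        _, act_b = nf.fingerprint(b, p, return_activations=True)
        changed = 8
        for j in range(9):
            for li, level in enumerate(p.write_levels):
                if abs(j - changed) > level:
                    assert np.allclose(act_a[j, li], act_b[j, li], atol=1e-12), (j, level)
        # sanity: the write of an atom near the change does differ
        assert not np.allclose(act_a[8, 1], act_b[8, 1], atol=1e-6)


class TestGradients:
    def test_finite_difference_agreement(self, rng):
        for smiles in ["CCO", "c1ccccc1", "CC(=O)N"]:
            mol = parse_molecule(smiles)
            p = nf.init_params(2, 5, seed=int(rng.integers(1000)))
            up = rng.normal(size=5)
            grads = nf.fingerprint_gradients(mol, p, up)
            eps = 1e-5
            checked = 0
            while checked < 20:
                key = p.keys()[int(rng.integers(len(p.keys())))]
                arr = p.get(key)
                idx = tuple(int(rng.integers(s)) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                fp_plus = float(up @ nf.fingerprint(mol, p).z)
                arr[idx] = orig - eps
                fp_minus = float(up @ nf.fingerprint(mol, p).z)
                arr[idx] = orig
                num = (fp_plus - fp_minus) / (2 * eps)
                ana = grads[key][idx]
                if max(abs(num), abs(ana)) < 1e-10:
                    continue  # skip dead weights for relative comparison
                assert abs(num - ana) / max(abs(num), abs(ana)) <= 1e-4
                checked += 1

    def test_unused_degree_filter_gradient_zero(self):
        mol = parse_molecule("CC")  # only degree-1 atoms
        p = nf.init_params(2, 4, seed=0)
        grads = nf.fingerprint_gradients(mol, p, np.ones(4))
        for l in range(2):
            for deg in (3, 4, 5):
                assert np.all(grads[("H", l, deg)] == 0)

    def test_gradient_linearity_in_upstream(self):
        mol = parse_molecule("CCO")
        p = nf.init_params(2, 4, seed=1)
        up = np.array([0.3, -1.0, 0.5, 2.0])
        g1 = nf.fingerprint_gradients(mol, p, up)
        g2 = nf.fingerprint_gradients(mol, p, 2 * up)
        for k in g1:
            assert np.allclose(2 * g1[k], g2[k], atol=1e-12)


class TestErrors:
    def test_degree_above_five_rejected(self):
        mol = parse_molecule("FS(F)(F)(F)(F)F")  # SF6: S with 6 heavy neighbors
        with pytest.raises(nf.FingerprintError, match="degree"):
            nf.featurize_molecule(mol)
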