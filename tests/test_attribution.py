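import numpy as np
import pytest
from rdkit import Chem

import consensusvs as cvs
from consensusvs.attribution import (
    AttributionError,
    BitAtomMap,
    BitEnvironment,
    FeatureAttribution,
    atom_weights,
    explain_compound,
    permutation_shap,
    render_atom_weights,
    retro_map_bits,
    shap_attributions,
)
from consensusvs.representations import featurize_mol


@pytest.fixture(scope="module")
def background(small_morgan_module):
    return small_morgan_module


@pytest.fixture(scope="module")
def small_morgan_module(request):
    # session fixtures are visible from module scope via getfixturevalue
    return request.getfixturevalue("small_morgan")


class TestPermutationShap:
    def test_constant_model_all_zero(self, rng):
        bg = rng.integers(0, 2, size=(8, 16)).astype(float)
        x = rng.integers(0, 2, size=16).astype(float)
        phi, base = permutation_shap(lambda X: np.full(len(X), 0.7), x, bg, seed=0)
        assert np.allclose(phi, 0.0)
        assert base == pytest.approx(0.7)

    def test_single_feature_model_gets_all_mass(self, rng):
        bg = np.zeros((6, 10))
        x = np.zeros(10)
        x[3] = 1.0
        phi, base = permutation_shap(lambda X: X[:, 3], x, bg, seed=1)
        assert phi[3] == pytest.approx(1.0)
        assert np.allclose(np.delete(phi, 3), 0.0)

    def test_additivity_exact(self, rng):
        bg = rng.integers(0, 2, size=(10, 24)).astype(float)
        x = rng.integers(0, 2, size=24).astype(float)

        def f(X):  # nonlinear model with interactions
            return 1 / (1 + np.exp(-(X[:, 0] * X[:, 1] + X[:, 2] - X[:, 5] * X[:, 7])))

        phi, base = permutation_shap(f, x, bg, n_permutations=3, seed=2)
        assert base + phi.sum() == pytest.approx(float(f(x[None, :])[0]), abs=1e-9)

    def test_linear_model_oracle(self, rng):
        """For f(x) = w.x + b the Shapley value of feature j is exactly
        w_j (x_j - mean background_j), independent of the permutation."""
        w = rng.normal(size=12)
        b = 0.3
        bg = rng.integers(0, 2, size=(9, 12)).astype(float)
        x = rng.integers(0, 2, size=12).astype(float)
        phi, base = permutation_shap(
            lambda X: X @ w + b, x, bg, n_permutations=1, seed=3
        )
        assert np.allclose(phi, w * (x - bg.mean(axis=0)), atol=1e-12)
        assert base == pytest.approx(float(bg.mean(axis=0) @ w + b))

    def test_seeded_determinism(self, rng):
        bg = rng.integers(0, 2, size=(8, 16)).astype(float)
        x = rng.integers(0, 2, size=16).astype(float)

        def f(X):
            return X.mean(axis=1)

        p1, _ = permutation_shap(f, x, bg, seed=11)
        p2, _ = permutation_shap(f, x, bg, seed=11)
        assert np.array_equal(p1, p2)

    def test_empty_background_rejected(self):
        with pytest.raises(AttributionError):
            permutation_shap(lambda X: X.sum(1), np.zeros(4), np.zeros((0, 4)))


class TestShapAttributions:
    def test_additivity_matches_model_ps(self, knn_model, background, small_dataset):
        smi = next(
            c.compound.smiles_std for c in small_dataset.compounds if c.label == "active"
        )
        attr = shap_attributions(
            knn_model, smi, background[:16], seed=4, n_permutations=1
        )
        x = featurize_mol(Chem.MolFromSmiles(smi), "morgan")[None, :].astype(float)
        ps = float(knn_model.predict_ps(x)[0])
        assert attr.base_value + attr.values.sum() == pytest.approx(ps, abs=1e-6)

    def test_non_morgan_model_rejected(self, small_dataset):
        from consensusvs.modeling import ModelSpec, features_for, train

        X = features_for(small_dataset, "pubchem")
        model = train(
            ModelSpec.create("RF", "pubchem", {"n_estimators": 20}, seed=0),
            small_dataset, features=X,
        )
        with pytest.raises(AttributionError):
            shap_attributions(model, "CCO", X[:4])


class TestRetroMap:
    def test_radius_zero_bits_are_single_atoms(self):
        bmap = retro_map_bits("CCO")
        r0 = [
            envs
            for envs in bmap.environments.values()
            if any(e.n_atoms == 1 for e in envs)
        ]
        assert r0, "expected at least one radius-0 environment"

    def test_benzene_symmetry_n_occ(self):
        bmap = retro_map_bits("c1ccccc1")
        # all six aromatic carbons share each environment bit
        assert set(bmap.environments) and all(
            bmap.n_occ(bit) == 6 for bit in bmap.environments
        )

    def test_mapped_atoms_subset_of_molecule(self):
        smi = "O=C(NCC)c1cc2ccccc2o1"
        bmap = retro_map_bits(smi)
        n = Chem.MolFromSmiles(smi).GetNumAtoms()
        for envs in bmap.environments.values():
            for env in envs:
                assert all(0 <= a < n for a in env.atoms)

    def test_on_bits_match_fingerprint(self):
        smi = "CC(=O)Nc1ccccc1"
        bmap = retro_map_bits(smi)
        fp = featurize_mol(Chem.MolFromSmiles(smi), "morgan")
        assert set(bmap.environments) == set(np.nonzero(fp)[0])


def _attr(values: dict, n_bits=16, name="m", on_bits=None):
    v = np.zeros(n_bits)
    for k, val in values.items():
        v[k] = val
    return FeatureAttribution(
        model_name=name, values=v, base_value=0.0,
        on_bits=tuple(on_bits if on_bits is not None else values),
    )


class TestAtomWeights:
    def test_single_environment_split(self):
        bmap = BitAtomMap(n_mol_atoms=4, environments={
            2: [BitEnvironment(atoms=(0, 1, 2))],
        })
        aw = atom_weights([_attr({2: 0.6})], bmap)
        assert np.allclose(aw.weights, [0.2, 0.2, 0.2, 0.0])

    def test_two_occurrences_scale_by_n_occ(self):
        bmap = BitAtomMap(n_mol_atoms=4, environments={
            1: [BitEnvironment(atoms=(0, 1)), BitEnvironment(atoms=(2, 3))],
        })
        aw = atom_weights([_attr({1: 0.4})], bmap)
        assert np.allclose(aw.weights, [0.1, 0.1, 0.1, 0.1])

    def test_atom_in_two_bits_accumulates(self):
        bmap = BitAtomMap(n_mol_atoms=3, environments={
            0: [BitEnvironment(atoms=(0, 1))],
            1: [BitEnvironment(atoms=(0, 1, 2))],
        })
        aw = atom_weights([_attr({0: 0.2, 1: 0.3})], bmap)
        assert aw.weights[0] == pytest.approx(0.1 + 0.1)

    def test_conservation_identity(self):
        bmap = BitAtomMap(n_mol_atoms=5, environments={
            0: [BitEnvironment(atoms=(0, 1))],
            3: [BitEnvironment(atoms=(1, 2, 3)), BitEnvironment(atoms=(2, 3, 4))],
        })
        attr = _attr({0: -0.25, 3: 0.4})
        aw = atom_weights([attr], bmap)
        assert aw.weights.sum() * 1 == pytest.approx((-0.25 + 0.4) / 1, abs=1e-12)

    def test_unmapped_scored_on_bit_warns(self):
        bmap = BitAtomMap(n_mol_atoms=2, environments={
            0: [BitEnvironment(atoms=(0,))],
        })
        attr = _attr({0: 0.2, 5: 0.1}, on_bits=(0, 5))
        with pytest.warns(UserWarning, match="missing from the bit-atom map"):
            atom_weights([attr], bmap)

    def test_mean_across_models(self):
        bmap = BitAtomMap(n_mol_atoms=2, environments={
            0: [BitEnvironment(atoms=(0,))],
        })
        a = _attr({0: 0.2}, name="m1")
        b = _attr({0: 0.6}, name="m2")
        aw = atom_weights([a, b], bmap)
        assert aw.weights[0] == pytest.approx(0.4)

    def test_identical_members_average_to_single(self):
        bmap = BitAtomMap(n_mol_atoms=2, environments={
            0: [BitEnvironment(atoms=(0, 1))],
        })
        single = atom_weights([_attr({0: 0.3}, name="m1")], bmap)
        double = atom_weights(
            [_attr({0: 0.3}, name="m1"), _attr({0: 0.3}, name="m2")], bmap
        )
        assert np.allclose(single.weights, double.weights)


class TestEndToEnd:
    def test_model_level_conservation_on_real_explanation(
        self, consensus_model, background, small_dataset
    ):
        smi = next(
            c.compound.smiles_std for c in small_dataset.compounds if c.label == "active"
        )
        attribution, attrs, bmap = explain_compound(
            consensus_model, smi, background[:16], seed=5, n_permutations=1
        )
        for attr in attrs:
            mapped_sum = sum(attr.values[b] for b in bmap.environments)
            model_sum = attribution.per_model[attr.model_name].sum()
            assert model_sum == pytest.approx(mapped_sum, abs=1e-9)

    def test_render_writes_svg(self, tmp_path, consensus_model, background, small_dataset):
        smi = small_dataset.compounds[0].compound.smiles_std
        attribution, _, _ = explain_compound(
            consensus_model, smi, background[:8], seed=6, n_permutations=1
        )
        out = tmp_path / "weights.svg"
        render_atom_weights(smi, attribution, str(out))
        text = out.read_text()
        assert text.startswith("<?xml") and "svg" in text

    def test_render_all_zero_weights_unshaded(self, tmp_path):
        smi = "CCO"
        n = Chem.MolFromSmiles(smi).GetNumAtoms()
        from consensusvs.attribution import AtomAttribution

        attribution = AtomAttribution(per_model={"m": np.zeros(n)}, weights=np.zeros(n))
        out = tmp_path / "zero.svg"
        render_atom_weights(smi, attribution, str(out))
        assert out.exists()
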