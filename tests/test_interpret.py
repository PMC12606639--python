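"""Shapley attribution axioms, MACCS grouping and counterfactual search."""

import numpy as np
import pytest

from amesqsar.featurize import compute_features
from amesqsar.interpret import (
    counterfactual_search,
    enumerate_analogs,
    maccs_key_groups,
    rank_and_group,
    shapley_attributions,
    tanimoto_distance,
)


class TestShapleyAxioms:
    def test_constant_model_gets_zero_attributions(self, rng):
        bg = rng.integers(0, 2, size=(30, 8)).astype(float)
        Xe = rng.integers(0, 2, size=(4, 8)).astype(float)
        summary = shapley_attributions(
            lambda X: np.full(len(X), 0.7), bg, Xe, n_samples=50, seed=0
        )
        assert np.allclose(summary.attributions, 0.0)
        assert summary.baseline == pytest.approx(0.7)

    def test_local_accuracy_on_every_explained_row(self, rng):
        """Efficiency axiom: baseline + sum of attributions = model output."""
        p = 20
        bg = rng.normal(size=(50, p))
        Xe = rng.normal(size=(3, p))
        w = rng.normal(size=p)

        def model(X):
            return 1.0 / (1.0 + np.exp(-(X @ w) / 3.0))

        summary = shapley_attributions(model, bg, Xe, n_samples=2048, seed=1)
        totals = summary.baseline + summary.attributions.sum(axis=1)
        assert np.allclose(totals, summary.explained_outputs, atol=0.02)

    def test_null_feature_gets_zero(self, rng):
        bg = rng.normal(size=(40, 5))
        Xe = rng.normal(size=(3, 5))

        def model(X):  # ignores feature 4 entirely
            return np.tanh(X[:, 0] + 0.5 * X[:, 1])

        summary = shapley_attributions(model, bg, Xe, n_samples=400, seed=2)
        assert np.allclose(summary.attributions[:, 4], 0.0)

    def test_symmetry_for_duplicated_features(self, rng):
        """Two identical columns share credit in expectation."""
        bg = np.repeat(rng.normal(size=(40, 1)), 2, axis=1)
        bg = np.hstack([bg, rng.normal(size=(40, 1))])
        Xe = np.array([[1.5, 1.5, -0.5]])

        def model(X):
            return X[:, 0] + X[:, 1] + 0.3 * X[:, 2]

        summary = shapley_attributions(model, bg, Xe, n_samples=3000, seed=3)
        phi = summary.attributions[0]
        assert phi[0] == pytest.approx(phi[1], abs=0.1)

    def test_deterministic_given_seed(self, rng):
        bg = rng.normal(size=(20, 4))
        Xe = rng.normal(size=(2, 4))
        model = lambda X: X.sum(axis=1)
        a = shapley_attributions(model, bg, Xe, n_samples=64, seed=9)
        b = shapley_attributions(model, bg, Xe, n_samples=64, seed=9)
        assert np.array_equal(a.attributions, b.attributions)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            shapley_attributions(
                lambda X: X.sum(axis=1), np.empty((0, 3)), np.zeros((1, 3)), n_samples=8
            )

    def test_planted_bit_ranks_first(self, planted600, maccs600):
        """The model's most important MACCS key co-varies with the planted rule."""
        from amesqsar.neuralnet import NetworkConfig, train_network

        ds, truth = planted600
        y = ds.labels()
        net = train_network(
            maccs600, y, NetworkConfig(hidden_sizes=(64,), epochs=60, seed=21)
        )
        rng = np.random.default_rng(17)
        bg = maccs600.values[rng.choice(maccs600.n, size=100, replace=False)]
        explain = maccs600.values[rng.choice(maccs600.n, size=12, replace=False)]
        summary = shapley_attributions(
            net, bg, explain, n_samples=150, seed=4, feature_names=maccs600.column_names
        )
        # keys perfectly co-varying with the rule are interchangeable by symmetry
        rule = truth["rule_match"].to_numpy()
        equivalent = {
            maccs600.column_names[j]
            for j in range(maccs600.p)
            if np.array_equal(maccs600.values[:, j].astype(bool), rule)
        }
        assert equivalent, "fixture should contain rule-tracking keys"
        top = summary.table().iloc[0]["feature"]
        assert top in equivalent


class TestMaccsGroups:
    @pytest.mark.parametrize(
        "key,group",
        [
            ("MACCS134", "halogen"),
            ("MACCS63", "nitrogen-containing"),
            ("MACCS84", "nitrogen-containing"),
            ("MACCS133", "nitrogen-containing"),
            ("MACCS102", "oxygen-containing"),
            ("MACCS72", "oxygen-containing"),
            ("MACCS126", "oxygen-containing"),
            ("MACCS125", "ring-related"),
            ("MACCS22", "ring-related"),
        ],
    )
    def test_known_key_assignments(self, key, group):
        assert maccs_key_groups()[key] == group

    def test_every_key_in_exactly_one_group(self):
        groups = maccs_key_groups()
        assert len(groups) == 167
        valid = {"halogen", "nitrogen-containing", "oxygen-containing", "ring-related", "other"}
        assert set(groups.values()) <= valid

    def test_rank_and_group_top_k(self, rng):
        bg = rng.integers(0, 2, size=(30, 6)).astype(float)
        Xe = bg[:5]
        model = lambda X: 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.1 * X[:, 2]
        names = [f"MACCS{i}" for i in (134, 63, 125, 22, 72, 84)]
        summary = shapley_attributions(model, bg, Xe, n_samples=300, seed=5, feature_names=names)
        with pytest.warns(UserWarning):
            top = rank_and_group(summary, top_k=100)
        assert (top["sign"] > 0).all()
        assert "group" in top.columns


class TestCounterfactuals:
    @staticmethod
    def nitro_detector(smiles: str) -> int:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        return int(mol.HasSubstructMatch(Chem.MolFromSmarts("[N+](=O)[O-]")))

    def test_only_flipping_candidate_returned(self):
        result = counterfactual_search(
            "c1ccccc1",
            ["O=[N+]([O-])c1ccccc1", "Cc1ccccc1"],
            self.nitro_detector,
        )
        assert result.analog_smiles == "O=[N+]([O-])c1ccccc1"
        assert result.label_base == 0 and result.label_analog == 1
        assert 0 < result.distance <= 1

    def test_no_flip_returns_none_with_warning(self):
        with pytest.warns(UserWarning):
            assert counterfactual_search("c1ccccc1", ["Cc1ccccc1"], self.nitro_detector) is None

    def test_empty_candidates_warns(self):
        with pytest.warns(UserWarning):
            assert counterfactual_search("c1ccccc1", [], self.nitro_detector) is None

    def test_nearer_flipping_candidate_wins(self):
        base = "Cc1ccccc1"
        near = "Cc1ccc(cc1)[N+](=O)[O-]"  # p-nitrotoluene
        far = "O=[N+]([O-])c1ccc2ccccc2c1O"
        d_near = tanimoto_distance(base, near)
        d_far = tanimoto_distance(base, far)
        assert d_near < d_far
        result = counterfactual_search(base, [far, near], self.nitro_detector)
        assert result.analog_smiles == near

    def test_returned_distance_always_positive(self):
        result = counterfactual_search(
            "c1ccccc1", ["O=[N+]([O-])c1ccccc1"], self.nitro_detector
        )
        assert result.distance > 0

    def test_analog_enumeration_single_edits(self):
        analogs = enumerate_analogs("Cc1ccccc1")
        assert analogs, "toluene should have analogs"
        from rdkit import Chem

        assert all(Chem.MolFromSmiles(s) is not None for s in analogs)
        assert "Cc1ccccc1" not in analogs
        # additions include a nitrotoluene; swaps include halotoluenes
        assert any("[N+](=O)[O-]" in s for s in analogs)

    def test_enumerated_analogs_feed_search(self):
        result = counterfactual_search("Cc1ccccc1", None, self.nitro_detector)
        assert result is not None
        assert result.label_analog == 1
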