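"""Feed-forward classifier training, prediction and cross-validation."""

import numpy as np
import pytest

from amesqsar.neuralnet import (
    HIDDEN_GRID,
    NetworkConfig,
    cross_validate,
    grid_configs,
    predict,
    train_network,
)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(42)
    n = 200
    X = np.vstack(
        [rng.normal(-2.0, 0.7, size=(n // 2, 2)), rng.normal(2.0, 0.7, size=(n // 2, 2))]
    )
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestTrainNetwork:
    def test_separable_data_fits_well(self, separable):
        X, y = separable
        net = train_network(X, y, NetworkConfig(hidden_sizes=(16,), epochs=50, seed=1))
        _, labels = predict(net, X)
        assert (labels == y).mean() >= 0.95

    def test_deterministic_given_seed(self, separable):
        X, y = separable
        cfg = NetworkConfig(hidden_sizes=(8,), epochs=10, seed=5)
        p1 = train_network(X, y, cfg).predict_proba(X)
        p2 = train_network(X, y, cfg).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_network(X, np.ones(10), NetworkConfig(epochs=1))

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            train_network(np.zeros((4, 2)), [0, 1, 2, 1], NetworkConfig(epochs=1))

    def test_both_optimizers_learn(self, separable):
        X, y = separable
        for opt in ("Adam", "Adamax"):
            net = train_network(
                X, y, NetworkConfig(hidden_sizes=(16,), optimizer=opt, epochs=50, seed=2)
            )
            _, labels = predict(net, X)
            assert (labels == y).mean() >= 0.95, opt

    def test_matches_sklearn_reference_on_separable_data(self, separable):
        """Independent cross-check: sklearn's MLP reaches the same regime."""
        from sklearn.neural_network import MLPClassifier

        X, y = separable
        ref = MLPClassifier(
            hidden_layer_sizes=(16,), solver="adam", max_iter=500, random_state=0
        ).fit(X, y)
        ours = train_network(
            X, y, NetworkConfig(hidden_sizes=(16,), optimizer="Adam", epochs=50, seed=2)
        )
        _, ours_labels = predict(ours, X)
        assert (ref.predict(X) == y).mean() >= 0.95
        assert (ours_labels == y).mean() >= 0.95


class TestPredict:
    def test_probability_bounds_and_threshold(self, separable, rng):
        X, y = separable
        net = train_network(X, y, NetworkConfig(hidden_sizes=(8,), epochs=5, seed=0))
        proba, labels = predict(net, rng.normal(size=(30, 2)))
        assert np.all((proba >= 0) & (proba <= 1))
        assert np.array_equal(labels, (proba >= 0.5).astype(int))

    def test_boundary_probability_is_positive_label(self):
        # degenerate zero-weight net outputs exactly sigmoid(0) = 0.5
        from amesqsar.neuralnet import TrainedNetwork

        net = TrainedNetwork(
            config=NetworkConfig(hidden_sizes=(2,)),
            weights=[np.zeros((3, 2)), np.zeros((2, 1))],
            biases=[np.zeros(2), np.zeros(1)],
            n_features=3,
        )
        proba, labels = predict(net, np.ones((1, 3)))
        assert proba[0] == 0.5 and labels[0] == 1

    def test_width_mismatch_rejected(self, separable):
        X, y = separable
        net = train_network(X, y, NetworkConfig(hidden_sizes=(4,), epochs=2, seed=0))
        with pytest.raises(ValueError, match="width"):
            predict(net, np.zeros((3, 5)))


class TestCrossValidate:
    def test_fold_partition_and_stratification(self, separable):
        X, y = separable
        report = cross_validate(X, y, NetworkConfig(hidden_sizes=(8,), epochs=5, seed=0), k=5, seed=1)
        assert report.k == 5 and len(report.per_fold) == 5
        mean, sd = report.mean_sd["accuracy"]
        vals = [m.accuracy for m in report.per_fold]
        assert min(vals) <= mean <= max(vals)

    def test_planted_rule_cv_balanced_accuracy(self, planted_cv_report):
        """The selected architecture recovers the planted substructure rule:
        10-fold CV balanced accuracy >= 0.9 on the n=600, 5%-noise library."""
        assert planted_cv_report.mean("balanced_accuracy") >= 0.9

    def test_cv_beats_majority_baseline_on_planted_data(self, planted_cv_report):
        assert planted_cv_report.mean("accuracy") > 0.55


def test_save_load_roundtrip(tmp_path, separable):
    from amesqsar.neuralnet import load_network, save_network

    X, y = separable
    net = train_network(X, y, NetworkConfig(hidden_sizes=(8, 4), epochs=5, seed=3))
    path = tmp_path / "net.npz"
    save_network(net, path)
    back = load_network(path)
    assert back.config == net.config
    assert np.array_equal(back.predict_proba(X), net.predict_proba(X))


class TestGridConfigs:
    def test_thirteen_families_give_78_models(self):
        fams = [f"fam{i}" for i in range(13)]
        assert len(grid_configs(fams)) == 78

    def test_one_family_gives_six(self):
        assert len(grid_configs(["MACCS"])) == 6

    def test_fixed_depth_and_optimizer_gives_one_per_family(self):
        fams = [f"fam{i}" for i in range(13)]
        fixed = grid_configs(fams, hidden_grid=((512, 128, 8),), optimizers=("Adamax",))
        assert len(fixed) == 13
        assert all(cfg.hidden_sizes == (512, 128, 8) for _, cfg in fixed)

    def test_grid_covers_cross_product(self):
        out = grid_configs(["a", "b"])
        combos = {(f, c.hidden_sizes, c.optimizer) for f, c in out}
        assert len(combos) == 2 * len(HIDDEN_GRID) * 2

    def test_empty_or_duplicate_families_rejected(self):
        with pytest.raises(ValueError):
            grid_configs([])
        with pytest.raises(ValueError):
            grid_configs(["a", "a"])
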