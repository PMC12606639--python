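"""Feature families, hygiene transforms and X-randomization."""

import numpy as np
import pytest

from amesqsar.featurize import (
    BUILTIN_FAMILY_NAMES,
    FeatureFamily,
    FeatureMatrix,
    clean_matrix,
    compute_features,
    correlation_filter,
    read_feature_tsv,
    register_external_family,
    write_feature_tsv,
    x_randomize,
)


def fm(values, names=None, ids=None):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        family=FeatureFamily("test"),
        values=values,
        column_names=names or [f"c{i}" for i in range(values.shape[1])],
        row_ids=ids or [str(i) for i in range(values.shape[0])],
    )


class TestComputeFeatures:
    def test_maccs_row_length_is_167(self):
        X = compute_features((["a"], ["CCO"]), "MACCS")
        assert X.p == 167

    def test_featurization_is_deterministic(self):
        X = compute_features((["a", "b"], ["CCO", "CCO"]), "ECFP")
        assert np.array_equal(X.values[0], X.values[1])

    def test_nitrobenzene_and_benzene_differ_in_maccs(self):
        X = compute_features(
            (["nb", "b"], ["O=[N+]([O-])c1ccccc1", "c1ccccc1"]), "MACCS"
        )
        assert np.any(X.values[0] != X.values[1])

    @pytest.mark.parametrize("family", BUILTIN_FAMILY_NAMES)
    def test_every_builtin_family_produces_a_row(self, family):
        X = compute_features((["a"], ["O=[N+]([O-])c1ccc(Cl)cc1"]), family)
        assert X.n == 1 and X.p > 0
        if family != "Descriptors2D":
            assert set(np.unique(X.values)) <= {0.0, 1.0}

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown feature family"):
            compute_features((["a"], ["CCO"]), "NoSuchFamily")

    def test_bad_smiles_names_offender(self):
        with pytest.raises(ValueError, match="xyz"):
            compute_features((["xyz"], ["C1CC"]), "MACCS")

    def test_external_family_joins_by_id(self):
        register_external_family("TestEmbed", {"a": [1.0, 2.0], "b": [3.0, 4.0]})
        X = compute_features((["b", "a"], ["CCO", "CCN"]), "TestEmbed")
        assert np.array_equal(X.values, [[3.0, 4.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="no row for id"):
            compute_features((["zz"], ["CCO"]), "TestEmbed")


class TestCleanMatrix:
    def test_non_finite_column_dropped_and_recorded(self):
        X = clean_matrix(fm([[1, np.nan], [2, 3]]))
        assert X.column_names == ["c0"]
        assert X.dropped_columns == ["c1"]

    def test_constant_column_dropped_only_with_flag(self):
        raw = fm([[0, 1], [0, 2]])
        assert clean_matrix(raw).p == 2
        assert clean_matrix(raw, drop_constant=True).column_names == ["c1"]

    def test_all_dropped_is_an_error(self):
        with pytest.raises(ValueError, match="all columns"):
            clean_matrix(fm([[np.inf], [1.0]]))


class TestCorrelationFilter:
    def test_identical_columns_keep_one(self):
        X = correlation_filter(fm([[1, 1], [2, 2], [3, 3]]))
        assert X.p == 1

    def test_hand_built_matrix_keeps_larger_variance_member(self):
        # c0 and c1 correlate at r ~ 0.997 with var(c1) > var(c0); c2 is
        # nearly uncorrelated with both (|r| < 0.4 by direct computation)
        X = fm(
            [
                [1.0, 2.0, 5.0],
                [2.0, 4.1, 1.0],
                [3.0, 6.0, 4.0],
                [4.0, 8.2, 4.5],
                [5.0, 10.0, 2.0],
            ]
        )
        corr = np.corrcoef(X.values, rowvar=False)
        assert abs(corr[0, 1]) > 0.9 and abs(corr[0, 2]) < 0.9 and abs(corr[1, 2]) < 0.9
        out = correlation_filter(X, threshold=0.9)
        assert out.column_names == ["c1", "c2"]
        assert out.dropped_columns == ["c0"]

    def test_no_pair_above_threshold_is_identity(self):
        rng = np.random.default_rng(0)
        X = fm(rng.normal(size=(50, 4)))
        out = correlation_filter(X, threshold=0.95)
        assert out.column_names == X.column_names

    def test_retained_pairs_below_threshold(self, rng):
        base = rng.normal(size=(40, 1))
        X = fm(np.hstack([base + 0.01 * rng.normal(size=(40, 3)), rng.normal(size=(40, 3))]))
        out = correlation_filter(X, threshold=0.9)
        corr = np.atleast_2d(np.corrcoef(out.values, rowvar=False))
        off = np.abs(corr - np.eye(out.p))
        assert off.max() <= 0.9 + 1e-12

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            correlation_filter(fm([[1.0, 2.0]]), threshold=1.5)


class TestXRandomize:
    def test_deterministic_and_row_multiset_preserved(self, rng):
        X = fm(rng.normal(size=(20, 3)))
        a = x_randomize(X, seed=4)
        b = x_randomize(X, seed=4)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, X.values)
        assert np.array_equal(
            np.sort(a.values, axis=0), np.sort(X.values, axis=0)
        )
        assert a.row_ids == X.row_ids  # labels stay put

    def test_inverse_permutation_restores_matrix(self, rng):
        X = fm(rng.normal(size=(15, 2)))
        shuffled = x_randomize(X, seed=8)
        perm = np.random.default_rng(8).permutation(X.n)
        inv = np.argsort(perm)
        assert np.array_equal(shuffled.values[inv], X.values)

    def test_per_column_mode_preserves_column_multisets(self, rng):
        X = fm(rng.normal(size=(12, 3)))
        out = x_randomize(X, seed=2, per_column=True)
        for j in range(3):
            assert np.array_equal(np.sort(out.values[:, j]), np.sort(X.values[:, j]))


def test_featurization_pure_function_of_smiles(small_planted):
    ds, _ = small_planted
    X1 = compute_features(ds, "MACCS")
    X2 = compute_features(ds, "MACCS")
    assert np.array_equal(X1.values, X2.values)


def test_tsv_roundtrip(tmp_path, rng):
    X = fm(rng.normal(size=(6, 3)))
    path = tmp_path / "X.tsv"
    write_feature_tsv(X, path)
    back = read_feature_tsv(path)
    assert back.row_ids == X.row_ids
    assert back.column_names == X.column_names
    assert np.allclose(back.values, X.values)
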