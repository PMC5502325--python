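"""Missingness filter, kNN imputation and 0-1 normalization."""

import numpy as np
import pytest
from sklearn.impute import KNNImputer as SkKNNImputer

from ptsdml.preprocess import (
    FoldPreprocessor,
    KNNImputer,
    MinMaxNormalizer,
    drop_high_missingness,
    knn_impute,
    minmax_normalize,
    preprocess_pipeline,
)
from ptsdml.simulate import SyntheticSpec, generate_cohort

from conftest import make_table


class TestMissingnessFilter:
    def test_strictly_greater_than_threshold(self):
        vals = np.ones((10, 3))
        vals[:6, 0] = np.nan  # 60% missing -> dropped
        vals[:5, 1] = np.nan  # exactly 50% -> retained
        table = make_table(vals)
        out, report = drop_high_missingness(table, threshold=0.5)
        assert out.variable_names == ["v1", "v2"]
        assert report.dropped_variables == [("v0", 0.6)]

    def test_no_missing_is_identity(self, rng):
        table = make_table(rng.standard_normal((5, 4)))
        out, report = drop_high_missingness(table)
        assert out.variable_names == table.variable_names
        assert report.dropped_variables == []

    def test_all_dropped_is_error(self):
        vals = np.full((4, 2), np.nan)
        vals[0] = 1.0
        with pytest.raises(ValueError, match="all variables"):
            drop_high_missingness(make_table(vals), threshold=0.5)


class TestKNNImpute:
    def test_nearest_neighbour_fill(self, toy_table):
        # nearest row to (0,0,?) on the observed coordinates is (0,0,5)
        out = knn_impute(toy_table, k=1)
        assert out.values[0, 2] == 5.0
        assert not out.missing_mask.any()

    def test_two_neighbour_mean(self, toy_table):
        out = knn_impute(toy_table, k=2)
        assert out.values[0, 2] == pytest.approx((5.0 + 1.0) / 2)

    def test_observed_cells_unchanged(self, toy_table):
        out = knn_impute(toy_table, k=2)
        obs = ~toy_table.missing_mask
        np.testing.assert_array_equal(out.values[obs], toy_table.values[obs])

    def test_complete_table_identity(self, rng):
        table = make_table(rng.standard_normal((6, 3)))
        out = knn_impute(table, k=2)
        np.testing.assert_array_equal(out.values, table.values)

    def test_idempotent(self, toy_table):
        once = knn_impute(toy_table, k=2)
        twice = knn_impute(once, k=2)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_k_clamped_with_warning(self, toy_table):
        with pytest.warns(UserWarning, match="clamped"):
            out = knn_impute(toy_table, k=10)
        assert not out.missing_mask.any()

    def test_discrete_values_rounded_to_levels(self):
        vals = np.array(
            [[0.0, 1.0], [0.1, 1.0], [0.05, 0.0], [2.0, np.nan]], dtype=float
        )
        table = make_table(vals, kinds=["continuous", "binary"])
        out = knn_impute(table, k=3)
        assert out.values[3, 1] in (0.0, 1.0)

    def test_matches_sklearn_on_shared_metric(self, rng):
        # with missingness confined to one column, the neighbour ordering of
        # the mutually-observed-coordinates metric coincides with sklearn's
        # nan-euclidean one, so plain-mean imputations must agree
        vals = rng.standard_normal((30, 6))
        miss = rng.choice(30, size=6, replace=False)
        vals[miss, 2] = np.nan
        table = make_table(vals)
        ours = knn_impute(table, k=4).values
        theirs = SkKNNImputer(n_neighbors=4, weights="uniform").fit_transform(vals)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_subject_with_no_observations_rejected(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="zero observed"):
            knn_impute(make_table(vals), k=1)


class TestMinMaxNormalize:
    def test_affine_map(self):
        table = make_table(np.array([[1.0], [3.0], [5.0]]))
        out, report = minmax_normalize(table)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])
        assert report.normalization_bounds["v0"] == (1.0, 5.0)

    def test_constant_column_zeroed_with_warning(self):
        table = make_table(np.array([[4.0], [4.0], [4.0]]))
        with pytest.warns(UserWarning, match="constant"):
            out, _ = minmax_normalize(table)
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 0.0, 0.0])

    def test_test_values_not_clipped(self):
        train = make_table(np.array([[1.0], [3.0]]))
        norm = MinMaxNormalizer().fit(train)
        test = make_table(np.array([[5.0]]))
        assert norm.transform(test).values[0, 0] == pytest.approx(2.0)

    def test_requires_complete_table(self):
        with pytest.raises(ValueError, match="missing"):
            minmax_normalize(make_table(np.array([[1.0], [np.nan]])))


class TestPipeline:
    def test_filter_impute_normalize_contract(self):
        table, _, _ = generate_cohort(SyntheticSpec(seed=3))
        out, report = preprocess_pipeline(table)
        assert not out.missing_mask.any()
        assert np.all(out.values >= 0.0) and np.all(out.values <= 1.0)
        # the forced high-missingness columns were eliminated
        assert len(report.dropped_variables) >= 1
        assert all(frac > 0.5 for _, frac in report.dropped_variables)

    def test_fold_preprocessor_uses_train_statistics(self, rng):
        vals = rng.standard_normal((24, 4))
        vals[3, 1] = np.nan
        train = make_table(vals)
        pre = FoldPreprocessor(impute_k=3)
        train_p = pre.fit_transform(train)
        assert np.all((0.0 <= train_p.values) & (train_p.values <= 1.0))
        test = make_table(rng.standard_normal((5, 4)) * 3.0)
        test_p = pre.transform(test)
        # held-out values outside the training range stay outside [0, 1]
        assert (test_p.values < 0).any() or (test_p.values > 1).any()
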