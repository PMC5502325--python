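"""Repeated nested cross-validation protocol."""

import warnings

import numpy as np
import pytest

from ptsdml.cohort import TargetVector
from ptsdml.crossval import inner_select, make_cv_plan, run_rnncv
from ptsdml.models import ModelSpec, small_grid
from ptsdml.simulate import SyntheticSpec, generate_cohort, noise_spec

from conftest import make_table


def cohort_labels(n=163, n_pos=11, seed=0):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, n_pos, replace=False)] = 1
    return TargetVector(y)


class TestCVPlan:
    def test_fold_sizes_are_fifths(self):
        plan = make_cv_plan(cohort_labels(), n_folds=5, n_repeats=3, seed=1)
        for r in range(3):
            sizes = sorted(
                len(plan.test_index(r, f)) for f in range(5)
            )
            assert sizes == [32, 32, 33, 33, 33]

    def test_stratification_spreads_positives(self):
        labels = cohort_labels()
        plan = make_cv_plan(labels, n_folds=5, n_repeats=5, seed=2)
        for r in range(5):
            per_fold = [
                int(labels.labels[plan.test_index(r, f)].sum()) for f in range(5)
            ]
            assert sorted(per_fold) in ([2, 2, 2, 2, 3], [2, 2, 2, 3, 3])
            assert sum(per_fold) == 11

    def test_partition_property(self):
        plan = make_cv_plan(cohort_labels(), n_folds=5, n_repeats=4, seed=3)
        for r in range(4):
            seen = np.concatenate([plan.test_index(r, f) for f in range(5)])
            assert sorted(seen) == list(range(163))

    def test_same_seed_identical(self):
        a = make_cv_plan(cohort_labels(), seed=7)
        b = make_cv_plan(cohort_labels(), seed=7)
        assert np.array_equal(a.assignments, b.assignments)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_cv_plan(cohort_labels(n=4, n_pos=2), n_folds=5)

    def test_few_positives_warns(self):
        with pytest.warns(UserWarning, match="positives"):
            make_cv_plan(cohort_labels(n=60, n_pos=3), n_folds=5, n_repeats=1)


class TestInnerSelect:
    def test_single_spec_grid_degenerate(self, rng):
        spec = ModelSpec.make("logistic")
        out = inner_select(rng.standard_normal((30, 2)),
                           rng.binomial(1, 0.5, 30), [spec])
        assert out == spec

    def test_correct_model_family_wins_on_linear_signal(self):
        wins = 0
        trials = 8
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            n = 250
            X = rng.standard_normal((n, 6))
            y = (X @ np.r_[1.5, 1.0, np.zeros(4)]
                 + rng.logistic(size=n) > 0).astype(int)
            grid = [
                ModelSpec.make("svm_linear", C=1.0),
                ModelSpec.make("svm_poly", C=1.0, degree=3),
            ]
            # cross-family grid: the linear spec should usually win
            if inner_select(X, y, grid, seed=seed).family == "svm_linear":
                wins += 1
        assert wins >= trials // 2 + 1

    def test_noise_still_returns_a_grid_member(self, rng):
        X = rng.standard_normal((60, 5))
        y = rng.binomial(1, 0.3, 60)
        y[:2] = [0, 1]
        grid = small_grid("lasso")
        assert inner_select(X, y, grid, seed=0) in grid


class TestRunRNNCV:
    def test_every_subject_scored_out_of_fold(self):
        # the protocol's own assertion guarantees each subject is scored
        # exactly once per repeat by a model that never saw it; here we also
        # check the reported estimate's bookkeeping
        table, target, _ = generate_cohort(noise_spec(seed=4))
        plan = make_cv_plan(target, n_folds=5, n_repeats=2, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_rnncv(
                table, target, ["logistic"], plan,
                grids={"logistic": small_grid("logistic")}, seed=4,
            )["logistic"]
        assert res.per_repeat_auc.shape == (2,)
        assert res.mean_auc == pytest.approx(res.per_repeat_auc.mean())
        assert res.sd_auc == pytest.approx(res.per_repeat_auc.std(ddof=1))
        assert len(res.chosen_specs) == 2 * 5

    def test_signal_cohort_beats_chance(self):
        spec = SyntheticSpec(
            n_subjects=400, n_variables=20, n_parents=3,
            n_correlated_distractors=0, missing_rate=0.0,
            high_missing_columns=0,
            parent_effects=(1.5, 1.2, 1.0), seed=6,
        )
        table, target, truth = generate_cohort(spec)
        plan = make_cv_plan(target, n_folds=5, n_repeats=2, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_rnncv(
                table, target, ["lasso"], plan,
                grids={"lasso": small_grid("lasso")}, seed=6,
            )["lasso"]
        assert res.mean_auc > 0.72
        assert res.mean_auc <= truth.bayes_auc + 0.05

    def test_repeat_averaging_tightens_the_estimate(self):
        # the spread of the mean over independent repeat blocks shrinks as
        # more repeats are averaged
        table, target, _ = generate_cohort(noise_spec(seed=8))
        plan = make_cv_plan(target, n_folds=5, n_repeats=8, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_rnncv(
                table, target, ["logistic"], plan,
                grids={"logistic": small_grid("logistic")}, seed=8,
            )["logistic"]
        singles = res.per_repeat_auc
        pairs = singles.reshape(4, 2).mean(axis=1)
        assert pairs.std() <= singles.std() + 1e-12

    def test_mismatched_plan_rejected(self):
        table, target, _ = generate_cohort(noise_spec(seed=1, n_subjects=60))
        plan = make_cv_plan(cohort_labels(n=50, n_pos=5), n_repeats=1)
        with pytest.raises(ValueError, match="plan"):
            run_rnncv(table, target, ["logistic"], plan)
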