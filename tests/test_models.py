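"""Classifier adapters, stepwise selection and AUC scoring."""

import itertools

import numpy as np
import pytest

from ptsdml.models import (
    FAMILIES,
    ModelSpec,
    _fit_logit_aic,
    compute_auc,
    default_grid,
    fit_score,
    stepwise_select,
)


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(case > control) with ties at 1/2."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = 0.0
    for c in cases:
        for d in controls:
            wins += 1.0 if c > d else (0.5 if c == d else 0.0)
    return wins / (len(cases) * len(controls))


class TestAUC:
    def test_perfect_ranking(self):
        assert compute_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_tied_pair_counts_half(self):
        auc = compute_auc(np.array([0.7, 0.5, 0.5, 0.3]), np.array([1, 1, 0, 0]))
        assert auc == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 51))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        labels = rng.binomial(1, 0.3, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert compute_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.binomial(1, 0.4, 40)
        labels[:2] = [0, 1]
        a = compute_auc(scores, labels)
        assert compute_auc(np.exp(3 * scores) + 7, labels) == pytest.approx(a)

    def test_label_reversal(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.binomial(1, 0.4, 40)
        labels[:2] = [0, 1]
        assert compute_auc(scores, 1 - labels) == pytest.approx(
            1 - compute_auc(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestModelSpec:
    def test_json_round_trip(self):
        spec = ModelSpec.make("svm_rbf", C=10.0, gamma=0.1,
                              feature_subset=["a", "b"])
        assert ModelSpec.from_json(spec.to_json()) == spec

    def test_illegal_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            ModelSpec.make("svm_linear", gamma=1.0)

    def test_grids_exist_for_every_family(self):
        for fam in FAMILIES:
            grid = default_grid(fam)
            assert grid and all(s.family == fam for s in grid)


class TestFitScore:
    def _separable(self, rng, n=60):
        y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)]
        X = rng.standard_normal((n, 2)) + np.where(y[:, None] == 1, 3.0, -3.0)
        return X, y

    @pytest.mark.parametrize(
        "family", ["svm_linear", "svm_rbf", "random_forest", "lasso",
                   "logistic", "stepwise_logistic"]
    )
    def test_separable_problem_ranked_correctly(self, family, rng):
        X, y = self._separable(rng)
        spec = ModelSpec.make(family) if family != "random_forest" else (
            ModelSpec.make(family, n_estimators=50)
        )
        scores = fit_score(spec, X, y, X, seed=0)
        assert compute_auc(scores, y) == 1.0

    def test_logistic_monotone_in_single_feature(self, rng):
        x = np.linspace(-2, 2, 50).reshape(-1, 1)
        y = (x[:, 0] + 0.3 * rng.standard_normal(50) > 0).astype(int)
        test = np.linspace(-3, 3, 20).reshape(-1, 1)
        scores = fit_score(ModelSpec.make("logistic"), x, y, test)
        assert np.all(np.diff(scores) > 0)

    def test_lasso_extreme_penalty_zeroes_scores(self, rng):
        X = rng.standard_normal((80, 10))
        y = rng.binomial(1, 0.5, 80)
        y[:2] = [0, 1]
        scores = fit_score(ModelSpec.make("lasso", C=1e-8), X, y, X)
        assert np.ptp(scores) == pytest.approx(0.0, abs=1e-9)

    def test_single_class_training_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="single class"):
            fit_score(ModelSpec.make("logistic"), X, np.ones(10, dtype=int), X)

    def test_feature_subset_respected(self, rng):
        X, y = self._separable(rng)
        X = np.column_stack([rng.standard_normal(len(y)), X])
        spec = ModelSpec.make("logistic", feature_subset=["f1", "f2"])
        scores = fit_score(spec, X, y, X, feature_names=["f0", "f1", "f2"])
        assert compute_auc(scores, y) == 1.0


class TestStepwise:
    def test_finds_planted_signal(self, rng):
        n = 500
        X = rng.standard_normal((n, 11))
        y = (1.5 * X[:, 4] + rng.logistic(size=n) > 0).astype(int)
        names = [f"x{j}" for j in range(11)]
        assert "x4" in stepwise_select(X, y, names)

    def test_agrees_with_exhaustive_hill_climb_oracle(self, rng):
        # independent oracle: tabulate AIC over all 2^4 subsets, then walk
        # the same forward/backward move rules over the table
        for trial in range(4):
            n = 120
            X = rng.standard_normal((n, 4))
            y = (X[:, 0] - 0.8 * X[:, 2] + rng.logistic(size=n) > 0).astype(int)
            names = ["a", "b", "c", "d"]
            aic = {
                frozenset(s): _fit_logit_aic(X[:, list(s)], y)
                for r in range(5)
                for s in itertools.combinations(range(4), r)
            }
            cur: frozenset = frozenset()
            improved = True
            while improved:
                improved = False
                adds = [cur | {j} for j in range(4) if j not in cur]
                if adds:
                    best = min(adds, key=lambda s: aic[s])
                    if aic[best] < aic[cur] - 1e-9:
                        cur, improved = best, True
                if len(cur) > 1:
                    drops = [cur - {j} for j in cur]
                    best = min(drops, key=lambda s: aic[s])
                    if aic[best] < aic[cur] - 1e-9:
                        cur, improved = best, True
            expected = sorted(names[j] for j in cur)
            assert stepwise_select(X, y, names) == expected

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError, match="at least one"):
            stepwise_select(np.empty((10, 0)), np.zeros(10), [])
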