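"""Repeated nested N-fold cross-validation (RNNCV).

The outer loop estimates generalisation error: each repeat partitions the
cohort into N stratified folds (N = 5 by default, i.e. an 80/20 split used
five times so every subject is held out exactly once), and the whole scheme
is repeated (30 times in the reference protocol) under fresh fold
assignments to reduce split variance.  Inside each outer training set an
inner (N-1)-fold loop picks the hyperparameter grid point with the best mean
AUC (model selection).  Preprocessing statistics (imputation donors,
normalization bounds) and any feature selection are computed on outer
training data only, so the outer estimates are unbiased: no model is scored
on a subject it was exposed to.

Per repeat, the held-out scores of all outer folds are pooled into a single
ROC; with only 2-3 cases per fold a per-fold AUC would be too unstable.  The
reported mean and SD are across repeats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable, TargetVector
from .hiton import select_within_fold
from .models import ModelSpec, compute_auc, default_grid, fit_score
from .preprocess import FoldPreprocessor

log = logging.getLogger(__name__)


@dataclass
class CVPlan:
    """Reproducible fold assignments: ``assignments[r, i]`` is subject i's
    test fold in repeat r."""

    n_subjects: int
    n_folds: int
    n_repeats: int
    stratified: bool
    assignments: np.ndarray
    seed: int

    def test_index(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)

    def train_index(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] != fold)


@dataclass
class PerformanceEstimate:
    """Per-repeat pooled AUCs with their mean and SD, plus provenance."""

    per_repeat_auc: np.ndarray
    mean_auc: float
    sd_auc: float
    chosen_specs: dict = field(default_factory=dict)
    selected_features: dict = field(default_factory=dict)

    @classmethod
    def from_aucs(cls, aucs, chosen_specs=None, selected_features=None):
        aucs = np.asarray(aucs, dtype=float)
        sd = float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0
        return cls(
            per_repeat_auc=aucs,
            mean_auc=float(aucs.mean()),
            sd_auc=sd,
            chosen_specs=chosen_specs or {},
            selected_features=selected_features or {},
        )


def make_cv_plan(
    labels: TargetVector | np.ndarray,
    n_folds: int = 5,
    n_repeats: int = 30,
    stratified: bool = True,
    seed: int = 0,
) -> CVPlan:
    """Draw reproducible (stratified) fold assignments for every repeat."""
    y = labels.labels if isinstance(labels, TargetVector) else np.asarray(labels)
    n = y.shape[0]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError("more folds than subjects")
    n_pos = int(y.sum())
    if stratified and 0 < n_pos < n_folds:
        warnings.warn(
            f"only {n_pos} positives for {n_folds} stratified folds; "
            "some test folds will lack cases",
            stacklevel=2,
        )
    assignments = np.empty((n_repeats, n), dtype=int)
    rng = np.random.default_rng(seed)
    for r in range(n_repeats):
        rs = int(rng.integers(2**31 - 1))
        if stratified and n_pos > 0 and n - n_pos > 0:
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                       random_state=rs)
            splits = splitter.split(np.zeros(n), y)
        else:
            perm = np.random.default_rng(rs).permutation(n)
            splits = (
                (None, perm[f::n_folds]) for f in range(n_folds)
            )
        for f, (_, test_idx) in enumerate(splits):
            assignments[r, test_idx] = f
    return CVPlan(
        n_subjects=n,
        n_folds=n_folds,
        n_repeats=n_repeats,
        stratified=stratified,
        assignments=assignments,
        seed=seed,
    )


def inner_select(
    train_X: np.ndarray,
    train_y: np.ndarray,
    family_grid: Sequence[ModelSpec],
    n_folds: int = 4,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> ModelSpec:
    """Pick the grid point with the highest pooled inner-CV AUC.

    Ties break to the earliest grid point; a grid of one skips the inner CV
    entirely.
    """
    if len(family_grid) == 0:
        raise ValueError("empty hyperparameter grid")
    if len(family_grid) == 1:
        return family_grid[0]
    y = np.asarray(train_y)
    n_pos = int(y.sum())
    if n_pos < 2 or len(y) - n_pos < 2:
        # too few members of a class to stratify an inner CV
        return family_grid[0]
    n_folds = min(n_folds, n_pos, len(y) - n_pos)
    n_folds = max(n_folds, 2)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(np.zeros(len(y)), y))
    best_spec = None
    best_auc = -np.inf
    failures = 0
    for spec in family_grid:
        pooled_scores = np.empty(len(y))
        try:
            for tr, te in splits:
                pooled_scores[te] = fit_score(
                    spec, train_X[tr], y[tr], train_X[te],
                    feature_names=feature_names, seed=seed,
                )
            auc = compute_auc(pooled_scores, y)
        except ValueError:
            failures += 1
            continue
        if auc > best_auc + 1e-12:
            best_auc = auc
            best_spec = spec
    if best_spec is None:
        raise ValueError("every grid point failed to fit")
    return best_spec


FeatureSelector = Callable[[CohortTable, TargetVector], list[str]]


def hiton_selector(
    alpha: float = 0.05, max_k: int = 3, ci_test: str = "auto"
) -> FeatureSelector:
    """Feature selector running HITON-PC on a (training) table."""

    def select(table: CohortTable, target: TargetVector) -> list[str]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pc = select_within_fold(table, target, alpha=alpha, max_k=max_k,
                                    ci_test=ci_test)
        return pc.selected

    return select


def univariate_selector(alpha: float = 0.05) -> FeatureSelector:
    """Feature selector keeping variables univariately associated with the
    target (p <= alpha)."""
    from .citest import association_rank

    def select(table: CohortTable, target: TargetVector) -> list[str]:
        return [name for name, _ in association_rank(target, table, alpha=alpha)]

    return select


def run_rnncv(
    table: CohortTable,
    labels: TargetVector,
    families: Sequence[str],
    plan: CVPlan,
    grids: dict[str, Sequence[ModelSpec]] | None = None,
    feature_selector: FeatureSelector | None = None,
    selector_scope: str = "fold",
    inner_folds: int | None = None,
    impute_k: int = 10,
    pooling: str = "fold_ranks",
    seed: int = 0,
) -> dict[str, PerformanceEstimate]:
    """Run the full RNNCV protocol; returns one estimate per family.

    ``pooling`` controls the per-repeat AUC: 'fold_ranks' (default) replaces
    each fold's test scores by their within-fold midranks before pooling —
    different folds' models need not share a score scale, and raw pooling is
    measurably pessimistic under the null for probability-scaled families;
    'scores' pools the raw scores.  ``selector_scope='full'`` deliberately
    runs the feature selector once on the complete data before
    cross-validation — the leakage mode that the protocol exists to avoid,
    kept only to demonstrate selection bias.
    """
    if selector_scope not in ("fold", "full"):
        raise ValueError("selector_scope must be 'fold' or 'full'")
    if pooling not in ("fold_ranks", "scores"):
        raise ValueError("pooling must be 'fold_ranks' or 'scores'")
    y = labels.labels
    if plan.n_subjects != len(y):
        raise ValueError("plan does not match the cohort")
    grids = grids or {}
    inner_folds = inner_folds if inner_folds is not None else plan.n_folds - 1
    rng = np.random.default_rng(seed)

    full_selection: list[str] | None = None
    if feature_selector is not None and selector_scope == "full":
        pre = FoldPreprocessor(impute_k=impute_k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full_table = pre.fit_transform(table)
        full_selection = feature_selector(full_table, labels)

    aucs: dict[str, list[float]] = {f: [] for f in families}
    chosen: dict[str, dict] = {f: {} for f in families}
    feats: dict = {}

    for r in range(plan.n_repeats):
        pooled: dict[str, np.ndarray] = {
            f: np.full(plan.n_subjects, np.nan) for f in families
        }
        for fold in range(plan.n_folds):
            tr_idx = plan.train_index(r, fold)
            te_idx = plan.test_index(r, fold)
            ytr = y[tr_idx]
            if np.unique(ytr).size < 2:
                log.warning("repeat %d fold %d: single-class training set", r, fold)
                for f in families:
                    pooled[f][te_idx] = 0.5
                continue
            train_t = table.select_subjects(tr_idx)
            test_t = table.select_subjects(te_idx)
            pre = FoldPreprocessor(impute_k=impute_k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train_p = pre.fit_transform(train_t)
                test_p = pre.transform(test_t)

            names = list(train_p.variable_names)
            if feature_selector is not None:
                if selector_scope == "full":
                    subset = [n for n in full_selection if n in names]
                else:
                    subset = feature_selector(
                        train_p, labels.subset(tr_idx)
                    )
                feats[(r, fold)] = list(subset)
                if subset:
                    col = [names.index(n) for n in subset]
                    Xtr = train_p.values[:, col]
                    Xte = test_p.values[:, col]
                    sub_names = list(subset)
                else:
                    Xtr = train_p.values[:, :0]
                    Xte = test_p.values[:, :0]
                    sub_names = []
            else:
                Xtr, Xte, sub_names = train_p.values, test_p.values, names

            for fam in families:
                fold_seed = int(rng.integers(2**31 - 1))
                if Xtr.shape[1] == 0:
                    pooled[fam][te_idx] = 0.5
                    continue
                grid = list(grids.get(fam, default_grid(fam)))
                spec = inner_select(
                    Xtr, ytr, grid, n_folds=inner_folds, seed=fold_seed,
                    feature_names=sub_names,
                )
                chosen[fam][(r, fold)] = spec
                scores = fit_score(
                    spec, Xtr, ytr, Xte, feature_names=sub_names, seed=fold_seed
                )
                if pooling == "fold_ranks":
                    # within-fold midranks scaled to (0, 1): fold models need
                    # not share a score scale or offset
                    scores = rankdata(scores) / (len(scores) + 1.0)
                pooled[fam][te_idx] = scores

        for fam in families:
            scores = pooled[fam]
            assert not np.isnan(scores).any(), "a subject was never scored"
            aucs[fam].append(compute_auc(scores, y))

    return {
        fam: PerformanceEstimate.from_aucs(
            aucs[fam], chosen_specs=chosen[fam], selected_features=dict(feats)
        )
        for fam in families
    }
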