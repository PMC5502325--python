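"""Label-shuffling significance testing and bootstrap stability ranking.

The label-shuffling test reruns the entire cross-validation protocol on
cohorts whose outcomes have been randomly permuted.  It serves two purposes:
the null mean AUC measures protocol bias (an unbiased protocol centres on
0.5), and the null distribution yields a one-sided p-value for the observed
predictivity.  Bootstrap stability reruns HITON-PC on resampled cohorts and
ranks variables by how often they are selected; high-frequency variables are
deemed robust causal candidates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, TargetVector
from .crossval import (
    CVPlan,
    FeatureSelector,
    make_cv_plan,
    run_rnncv,
)
from .hiton import run_hiton_pc
from .models import ModelSpec

log = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed_auc: float
    null_aucs: np.ndarray
    null_mean: float
    null_ci95: tuple[float, float]
    p_one_sided: float

    @classmethod
    def from_null(cls, observed: float, null_aucs) -> "PermutationResult":
        null_aucs = np.asarray(null_aucs, dtype=float)
        # add-one estimator: p > 0 even when no null value reaches the
        # observed AUC, counting "equal or higher" null draws
        p = (1.0 + np.sum(null_aucs >= observed)) / (1.0 + null_aucs.size)
        lo, hi = np.percentile(null_aucs, [2.5, 97.5])
        return cls(
            observed_auc=float(observed),
            null_aucs=null_aucs,
            null_mean=float(null_aucs.mean()),
            null_ci95=(float(lo), float(hi)),
            p_one_sided=float(p),
        )


@dataclass
class StabilityProfile:
    frequencies: dict[str, int]
    B: int
    threshold_count: int

    def __post_init__(self) -> None:
        for name, f in self.frequencies.items():
            if not 0 <= f <= self.B:
                raise ValueError(f"frequency of {name!r} outside [0, B]")

    @property
    def stable_set(self) -> list[str]:
        """Variables selected in strictly more than ``threshold_count``
        resamples."""
        return sorted(
            n for n, f in self.frequencies.items() if f > self.threshold_count
        )


def label_shuffle_test(
    table: CohortTable,
    labels: TargetVector,
    family: str,
    grid: list[ModelSpec] | None = None,
    feature_selector: FeatureSelector | None = None,
    n_permutations: int = 400,
    n_folds: int = 5,
    n_repeats: int = 30,
    null_repeats: int = 5,
    observed_auc: float | None = None,
    impute_k: int = 10,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of overall predictive signal for one family.

    Each permutation uniformly reshuffles the labels (class counts exactly
    preserved) and reruns the full RNNCV protocol under the same
    configuration; permutation reruns use ``null_repeats`` outer repeats
    (the null mean is repeat-count-invariant, and 400 full-fidelity reruns
    are rarely affordable).  The observed AUC is computed with the full
    ``n_repeats`` unless supplied.
    """
    if n_permutations < 20:
        warnings.warn(
            f"{n_permutations} permutations give coarse p-value resolution",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    grids = None if grid is None else {family: grid}

    if observed_auc is None:
        plan = make_cv_plan(
            labels, n_folds=n_folds, n_repeats=n_repeats,
            seed=int(rng.integers(2**31 - 1)),
        )
        est = run_rnncv(
            table, labels, [family], plan, grids=grids,
            feature_selector=feature_selector, impute_k=impute_k,
            seed=int(rng.integers(2**31 - 1)),
        )[family]
        observed_auc = est.mean_auc

    null_aucs = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(len(labels.labels))
        shuffled = TargetVector(labels.labels[perm])
        plan = make_cv_plan(
            shuffled, n_folds=n_folds, n_repeats=null_repeats,
            seed=int(rng.integers(2**31 - 1)),
        )
        est = run_rnncv(
            table, shuffled, [family], plan, grids=grids,
            feature_selector=feature_selector, impute_k=impute_k,
            seed=int(rng.integers(2**31 - 1)),
        )[family]
        null_aucs[b] = est.mean_auc

    result = PermutationResult.from_null(observed_auc, null_aucs)
    log.info(
        "%s: observed AUC %.3f, null mean %.3f [%.3f, %.3f], p = %.4g",
        family, result.observed_auc, result.null_mean, *result.null_ci95,
        result.p_one_sided,
    )
    return result


def bootstrap_stability(
    table: CohortTable,
    labels: TargetVector,
    B: int = 100,
    threshold_count: int = 20,
    alpha: float = 0.05,
    max_k: int = 3,
    ci_test: str = "auto",
    stratified: bool = True,
    seed: int = 0,
) -> StabilityProfile:
    """Selection frequency of each variable over B bootstrap resamples.

    Resamples draw n subjects with replacement (stratified by class by
    default, avoiding one-class resamples at 7% prevalence); HITON-PC runs on
    each resample and per-variable selection counts are recorded.  The table
    must be complete (preprocess first).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if table.missing_mask.any():
        raise ValueError("bootstrap_stability requires a complete table")
    rng = np.random.default_rng(seed)
    y = labels.labels
    n = len(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    counts: dict[str, int] = {name: 0 for name in table.variable_names}

    for b in range(B):
        while True:
            if stratified and pos.size and neg.size:
                idx = np.concatenate(
                    [
                        rng.choice(pos, size=pos.size, replace=True),
                        rng.choice(neg, size=neg.size, replace=True),
                    ]
                )
            else:
                idx = rng.choice(n, size=n, replace=True)
            if np.unique(y[idx]).size > 1:
                break
            log.info("redrawing a single-class bootstrap resample")
        boot_t = table.select_subjects(idx)
        boot_y = labels.subset(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pc = run_hiton_pc(
                boot_y, boot_t, alpha=alpha, max_k=max_k, ci_test=ci_test
            )
        for name in pc.selected:
            counts[name] += 1

    return StabilityProfile(frequencies=counts, B=B, threshold_count=threshold_count)


def rank_stable(profile: StabilityProfile) -> list[tuple[str, int]]:
    """Variables by descending selection frequency, name as tie-break."""
    return sorted(profile.frequencies.items(), key=lambda t: (-t[1], t[0]))
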