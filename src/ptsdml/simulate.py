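"""Synthetic cohorts with planted causal structure.

The generator emulates the statistical shape of an acute-injury paediatric
cohort: n = 163 subjects, p = 105 mixed binary / ordinal / continuous
predictors, and a rare binary outcome (~7% prevalence) driven by a small set
of planted "parent" variables through a logistic link.  Correlated
distractors — noisy copies of parents, conditionally independent of the
outcome given their parent — model information overlap between measured
variables; the remaining predictors are independent noise.  Missing entries
are injected completely at random, and a few columns are forced above 50%
missingness to exercise the missingness filter.  Because the planted target
is terminal (no children), the parents are exactly the target's
parents-and-children set and its Markov boundary, giving every recovery test
a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import CohortTable, TargetVector

DEFAULT_KIND_MIX = {"binary": 0.4, "categorical": 0.2, "continuous": 0.4}

#: log-odds per 1-SD of each (standardized) parent; chosen so the
#: Bayes-optimal AUC of the true linear predictor is about 0.80, the
#: performance regime of a well-powered acute-phase predictor
DEFAULT_EFFECTS = (0.78, 0.65, 0.52, 0.46, 0.39)


@dataclass
class SyntheticSpec:
    n_subjects: int = 163
    n_variables: int = 105
    n_parents: int = 5
    parent_effects: tuple[float, ...] | None = None
    target_prevalence: float = 0.07
    n_correlated_distractors: int = 10
    distractor_correlation: float = 0.7
    kind_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KIND_MIX)
    )
    missing_rate: float = 0.05
    high_missing_columns: int = 5
    high_missing_rate: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parent_effects is None:
            self.parent_effects = tuple(DEFAULT_EFFECTS[: self.n_parents]) + tuple(
                0.4 for _ in range(self.n_parents - len(DEFAULT_EFFECTS))
            )
        self.parent_effects = tuple(float(e) for e in self.parent_effects)
        if len(self.parent_effects) != self.n_parents:
            raise ValueError("parent_effects length must equal n_parents")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.n_parents + self.n_correlated_distractors + self.high_missing_columns > self.n_variables:
            raise ValueError("variable roles exceed n_variables")
        if not 0 < self.distractor_correlation < 1:
            raise ValueError("distractor_correlation must be in (0, 1)")
        if not np.isfinite(self.parent_effects).all():
            raise ValueError("effects must be finite")


@dataclass
class CausalGraphTruth:
    parents: list[str]
    distractor_map: dict[str, str]
    noise_variables: list[str]
    bayes_auc: float
    parent_effects: tuple[float, ...] = ()
    parent_kinds: tuple[str, ...] = ()
    intercept: float = 0.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_parent(rng: np.random.Generator, kind: str, n: int) -> np.ndarray:
    if kind == "binary":
        return rng.binomial(1, 0.5, size=n).astype(float)
    if kind == "categorical":
        return rng.integers(0, 4, size=n).astype(float)
    return rng.standard_normal(n)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _solve_intercept(
    rng: np.random.Generator,
    kinds: tuple[str, ...],
    effects: tuple[float, ...],
    prevalence: float,
    n_mc: int = 200_000,
    tol: float = 0.002,
) -> float:
    """Bisect the intercept so the Monte-Carlo marginal prevalence matches."""
    eta = np.zeros(n_mc)
    for kind, beta in zip(kinds, effects):
        eta += beta * _standardize(_draw_parent(rng, kind, n_mc))
    lo, hi = -30.0, 30.0
    if not _sigmoid(lo + eta).mean() <= prevalence <= _sigmoid(hi + eta).mean():
        raise ValueError("prevalence unreachable with the given effects")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        prev = _sigmoid(mid + eta).mean()
        if abs(prev - prevalence) < tol / 4:
            return mid
        if prev < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[CohortTable, TargetVector, CausalGraphTruth]:
    """Generate one cohort plus its causal ground truth.

    The same spec (including its seed) always yields a bit-identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_variables
    names = [f"V{j + 1:03d}" for j in range(p)]

    # role assignment: parents, distractors, then noise; high-missingness
    # columns are drawn from the noise block so ground truth survives the
    # missingness filter
    order = rng.permutation(p)
    parent_idx = order[: spec.n_parents]
    distr_idx = order[spec.n_parents : spec.n_parents + spec.n_correlated_distractors]
    noise_idx = order[spec.n_parents + spec.n_correlated_distractors :]

    kinds_pool = []
    mix_total = sum(spec.kind_mix.values())
    for kind, fracs in spec.kind_mix.items():
        kinds_pool += [kind] * int(round(p * fracs / mix_total))
    while len(kinds_pool) < p:
        kinds_pool.append("continuous")
    kinds_pool = kinds_pool[:p]
    rng.shuffle(kinds_pool)
    kinds = list(kinds_pool)
    for j in distr_idx:
        kinds[j] = "continuous"  # noisy copies are continuous by construction

    values = np.empty((n, p))
    z_parents = np.empty((n, spec.n_parents))
    for a, j in enumerate(parent_idx):
        col = _draw_parent(rng, kinds[j], n)
        values[:, j] = col
        z_parents[:, a] = _standardize(col)

    parent_kinds = tuple(kinds[j] for j in parent_idx)
    if spec.n_parents and any(e != 0 for e in spec.parent_effects):
        intercept = _solve_intercept(
            np.random.default_rng(rng.integers(2**31 - 1)),
            parent_kinds,
            spec.parent_effects,
            spec.target_prevalence,
        )
    else:
        intercept = float(np.log(spec.target_prevalence / (1 - spec.target_prevalence)))

    eta = z_parents @ np.asarray(spec.parent_effects) if spec.n_parents else np.zeros(n)
    labels = rng.binomial(1, _sigmoid(intercept + eta)).astype(int)

    rho = spec.distractor_correlation
    noise_scale = np.sqrt(1.0 / rho**2 - 1.0)
    distractor_map: dict[str, str] = {}
    for a, j in enumerate(distr_idx):
        src = a % max(spec.n_parents, 1) if spec.n_parents else None
        if src is None:
            values[:, j] = rng.standard_normal(n)
        else:
            values[:, j] = (
                z_parents[:, src] + noise_scale * rng.standard_normal(n)
            )
            distractor_map[names[j]] = names[parent_idx[src]]

    for j in noise_idx:
        values[:, j] = _draw_parent(rng, kinds[j], n)

    # MCAR missingness plus forced high-missingness columns (noise only)
    mask = rng.random((n, p)) < spec.missing_rate
    high_cols = noise_idx[: spec.high_missing_columns]
    for j in high_cols:
        mask[:, j] = rng.random(n) < spec.high_missing_rate
        # force strictly > 50% observed-missing fraction
        while mask[:, j].mean() <= 0.5:
            mask[rng.integers(n), j] = True
    # never blank out an entire row
    for i in np.flatnonzero(mask.all(axis=1)):
        mask[i, rng.integers(p)] = False
    values = np.where(mask, np.nan, values)

    table = CohortTable(
        values=values,
        variable_names=names,
        variable_kinds=kinds,
        missing_mask=mask,
        subject_ids=[f"S{i + 1:04d}" for i in range(n)],
    )
    target = TargetVector(labels=labels)

    truth = CausalGraphTruth(
        parents=[names[j] for j in parent_idx],
        distractor_map=distractor_map,
        noise_variables=[names[j] for j in noise_idx],
        bayes_auc=0.5,
        parent_effects=spec.parent_effects,
        parent_kinds=parent_kinds,
        intercept=intercept,
    )
    truth.bayes_auc = bayes_auc_oracle(truth, spec, n_mc=100_000)
    return table, target, truth


def bayes_auc_oracle(
    truth: CausalGraphTruth,
    spec: SyntheticSpec,
    n_mc: int = 100_000,
    seed: int | None = None,
    return_se: bool = False,
):
    """Monte-Carlo AUC of the true linear predictor — the Bayes upper bound.

    Draws a large synthetic population from the generative model, scores it
    with the true log-odds, and computes the case/control ranking
    probability.
    """
    rng = np.random.default_rng(spec.seed + 986_113 if seed is None else seed)
    if not truth.parents or all(e == 0 for e in truth.parent_effects):
        return (0.5, 0.0) if return_se else 0.5
    eta = np.zeros(n_mc)
    for kind, beta in zip(truth.parent_kinds, truth.parent_effects):
        eta += beta * _standardize(_draw_parent(rng, kind, n_mc))
    y = rng.binomial(1, _sigmoid(truth.intercept + eta))
    if y.min() == y.max():
        return (0.5, 0.0) if return_se else 0.5
    from .models import compute_auc

    auc = compute_auc(eta, y)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    # Hanley-McNeil standard error of the Mann-Whitney estimate
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
        / (n1 * n0)
    )
    return (float(auc), float(se)) if return_se else float(auc)


def noise_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A spec with zero planted effects: the pure-noise / null cohort."""
    kwargs = dict(
        n_parents=0,
        parent_effects=(),
        n_correlated_distractors=0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)
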