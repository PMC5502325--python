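"""Missingness filtering, k-nearest-neighbour imputation, 0-1 normalization.

Pipeline order is filter -> impute -> normalize.  The missingness filter uses
no outcome information and is applied once to the full table; imputation
donors and normalization bounds are refit inside each training fold of the
cross-validation protocol to avoid test-set leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    dropped_variables: list[tuple[str, float]] = field(default_factory=list)
    imputed_cell_count: int = 0
    normalization_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)


def drop_high_missingness(
    table: CohortTable, threshold: float = 0.5
) -> tuple[CohortTable, PreprocessReport]:
    """Remove variables whose missing fraction strictly exceeds ``threshold``.

    A variable missing exactly the threshold fraction is retained; survivor
    order is preserved.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = table.missing_mask.mean(axis=0)
    report = PreprocessReport()
    keep = []
    for j, name in enumerate(table.variable_names):
        if frac[j] > threshold:
            report.dropped_variables.append((name, float(frac[j])))
        else:
            keep.append(name)
    if not keep:
        raise ValueError("all variables exceed the missingness threshold")
    if report.dropped_variables:
        log.info(
            "dropped %d/%d variables with missingness > %.0f%%",
            len(report.dropped_variables),
            table.n_variables,
            100 * threshold,
        )
    return table.select_variables(keep), report


def _pairwise_mean_sq_dist(query: np.ndarray, donors: np.ndarray) -> np.ndarray:
    """Mean squared difference over mutually observed coordinates.

    Averaging (rather than summing) over the overlap keeps pairs with
    different numbers of mutually observed variables comparable.  Pairs with
    no overlap get +inf.
    """
    q = np.where(np.isnan(query), 0.0, query)
    d = np.where(np.isnan(donors), 0.0, donors)
    qo = (~np.isnan(query)).astype(float)
    do = (~np.isnan(donors)).astype(float)
    # sum over the overlap of (q - d)^2, expanded so masked cells drop out:
    # q^2 restricted to donor-observed + d^2 restricted to query-observed
    # - 2 q.d (zero-filled values already vanish outside the overlap)
    sq = (q**2) @ do.T - 2.0 * (q @ d.T) + qo @ (d**2).T
    overlap = qo @ do.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sq / overlap
    out[overlap == 0] = np.inf
    # numerical noise can push tiny negatives
    return np.maximum(out, 0.0)


class KNNImputer:
    """Unsupervised k-nearest-neighbour imputation.

    Each missing cell is filled with the (plain or inverse-distance weighted)
    mean of that variable over the k nearest donor subjects, with Euclidean
    distance computed on mutually observed variables.  Binary and categorical
    variables are rounded to the nearest observed level after averaging.
    The outcome is never an input: imputation is unsupervised by contract.
    """

    def __init__(self, k: int = 10, weighting: str = "uniform"):
        if k < 1:
            raise ValueError("k must be a positive integer")
        if weighting not in ("uniform", "inverse-distance"):
            raise ValueError("weighting must be uniform or inverse-distance")
        self.k = k
        self.weighting = weighting
        self._donors: CohortTable | None = None
        self._levels: list[np.ndarray | None] = []

    def fit(self, table: CohortTable) -> "KNNImputer":
        if table.missing_mask.all(axis=1).any():
            raise ValueError("a donor subject has zero observed values")
        self._donors = table
        self._levels = []
        for j, kind in enumerate(table.variable_kinds):
            if kind in ("binary", "categorical"):
                col = table.values[:, j]
                self._levels.append(np.unique(col[~np.isnan(col)]))
            else:
                self._levels.append(None)
        return self

    def transform(self, table: CohortTable) -> CohortTable:
        if self._donors is None:
            raise RuntimeError("imputer not fitted")
        donors = self._donors
        if table.variable_names != donors.variable_names:
            raise ValueError("variable names disagree with the fitted donors")
        if not table.missing_mask.any():
            return table.copy()
        if table.missing_mask.all(axis=1).any():
            raise ValueError("a subject has zero observed values")

        self_transform = table is donors or (
            table.n_subjects == donors.n_subjects
            and table.subject_ids == donors.subject_ids
        )
        k = self.k
        n_donor_max = donors.n_subjects - (1 if self_transform else 0)
        if n_donor_max < 1:
            raise ValueError("no donors available")
        if k > n_donor_max:
            warnings.warn(
                f"k={k} exceeds available donors; clamped to {n_donor_max}",
                stacklevel=2,
            )
            k = n_donor_max

        X = table.values.copy()
        dist = _pairwise_mean_sq_dist(table.values, donors.values)
        if self_transform:
            np.fill_diagonal(dist, np.inf)
        dval = donors.values
        for i in np.flatnonzero(table.missing_mask.any(axis=1)):
            miss_j = np.flatnonzero(table.missing_mask[i])
            for j in miss_j:
                avail = np.flatnonzero(~np.isnan(dval[:, j]) & np.isfinite(dist[i]))
                if avail.size == 0:
                    # no donor observes this variable at finite distance;
                    # fall back to the donor column mean
                    col = dval[:, j]
                    col = col[~np.isnan(col)]
                    if col.size == 0:
                        raise ValueError(
                            f"variable {donors.variable_names[j]!r} has no "
                            "observed donor values"
                        )
                    X[i, j] = col.mean()
                    continue
                order = avail[np.argsort(dist[i, avail], kind="stable")]
                nn = order[: min(k, order.size)]
                vals = dval[nn, j]
                if self.weighting == "inverse-distance":
                    w = 1.0 / np.maximum(np.sqrt(dist[i, nn]), 1e-12)
                    X[i, j] = float(np.average(vals, weights=w))
                else:
                    X[i, j] = float(vals.mean())
            # round discrete variables to the nearest legal level
            for j in miss_j:
                levels = self._levels[j]
                if levels is not None and levels.size:
                    X[i, j] = levels[np.argmin(np.abs(levels - X[i, j]))]

        return CohortTable(
            values=X,
            variable_names=list(table.variable_names),
            variable_kinds=list(table.variable_kinds),
            missing_mask=np.zeros_like(table.missing_mask),
            subject_ids=list(table.subject_ids),
        )


def knn_impute(
    table: CohortTable, k: int = 10, weighting: str = "uniform"
) -> CohortTable:
    """Impute a table against itself (each subject's own row excluded)."""
    imputer = KNNImputer(k=k, weighting=weighting).fit(table)
    return imputer.transform(table)


class MinMaxNormalizer:
    """Map each variable to [0, 1] by (x - min) / (max - min).

    Bounds are learned on the fitted (training) table and can be applied to
    held-out data; held-out values outside the training range are NOT clipped,
    so test values may fall outside [0, 1].  Constant variables map to zero.
    """

    def __init__(self) -> None:
        self.bounds_: dict[str, tuple[float, float]] | None = None

    def fit(self, table: CohortTable) -> "MinMaxNormalizer":
        lo = np.nanmin(table.values, axis=0)
        hi = np.nanmax(table.values, axis=0)
        self.bounds_ = {
            name: (float(lo[j]), float(hi[j]))
            for j, name in enumerate(table.variable_names)
        }
        return self

    def transform(self, table: CohortTable) -> CohortTable:
        if self.bounds_ is None:
            raise RuntimeError("normalizer not fitted")
        X = table.values.copy()
        constant = []
        for j, name in enumerate(table.variable_names):
            lo, hi = self.bounds_[name]
            if hi > lo:
                X[:, j] = (X[:, j] - lo) / (hi - lo)
            else:
                X[:, j] = 0.0
                constant.append(name)
        if constant:
            warnings.warn(
                f"{len(constant)} constant variable(s) mapped to zero: "
                f"{constant[:5]}",
                stacklevel=2,
            )
        return CohortTable(
            values=X,
            variable_names=list(table.variable_names),
            variable_kinds=list(table.variable_kinds),
            missing_mask=table.missing_mask.copy(),
            subject_ids=list(table.subject_ids),
        )


def minmax_normalize(table: CohortTable) -> tuple[CohortTable, PreprocessReport]:
    """Normalize a complete table to [0, 1]; returns the stored bounds."""
    if table.missing_mask.any():
        raise ValueError("normalize after imputation: missing values present")
    norm = MinMaxNormalizer().fit(table)
    out = norm.transform(table)
    report = PreprocessReport(normalization_bounds=dict(norm.bounds_ or {}))
    return out, report


class FoldPreprocessor:
    """Per-fold impute + normalize with training-only statistics.

    Fit on an (incomplete) training table: imputes the training rows against
    themselves, learns normalization bounds on the imputed training data.
    ``transform`` imputes held-out rows using training donors only and applies
    the training bounds.
    """

    def __init__(self, impute_k: int = 10, weighting: str = "uniform"):
        self.impute_k = impute_k
        self.weighting = weighting
        self.imputer_: KNNImputer | None = None
        self.normalizer_: MinMaxNormalizer | None = None
        self.train_: CohortTable | None = None

    def fit_transform(self, train: CohortTable) -> CohortTable:
        self.imputer_ = KNNImputer(k=self.impute_k, weighting=self.weighting)
        self.imputer_.fit(train)
        imputed = self.imputer_.transform(train)
        self.normalizer_ = MinMaxNormalizer().fit(imputed)
        self.train_ = imputed
        return self.normalizer_.transform(imputed)

    def transform(self, test: CohortTable) -> CohortTable:
        if self.imputer_ is None or self.normalizer_ is None:
            raise RuntimeError("fit_transform the training fold first")
        imputed = self.imputer_.transform(test)
        return self.normalizer_.transform(imputed)


def preprocess_pipeline(
    table: CohortTable,
    missingness_threshold: float = 0.5,
    impute_k: int = 10,
    weighting: str = "uniform",
) -> tuple[CohortTable, PreprocessReport]:
    """Full-table filter -> impute -> normalize (no fold structure)."""
    filtered, report = drop_high_missingness(table, missingness_threshold)
    report.imputed_cell_count = int(filtered.missing_mask.sum())
    if filtered.missing_mask.any():
        filtered = knn_impute(filtered, k=impute_k, weighting=weighting)
    normalized, nrep = minmax_normalize(filtered)
    report.normalization_bounds = nrep.normalization_bounds
    return normalized, report
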