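"""Cohort table I/O and binary target construction.

The analysis operates on a tab-delimited subjects-by-variables table with a
header row.  Variables are typed as binary, categorical (few integer levels)
or continuous; the outcome is a symptom score dichotomised at a cutoff
(default 38, the UCLA PTSD Reaction Index threshold for the PTSD group).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

log = logging.getLogger(__name__)

DEFAULT_NA_VALUES = ("", "NA", "NaN")
DEFAULT_CUTOFF = 38.0

KINDS = ("binary", "categorical", "continuous")


@dataclass
class CohortTable:
    """Subjects x variables matrix with names, kinds and a missingness mask.

    ``values`` is float64 with ``np.nan`` at missing cells; ``missing_mask``
    is True exactly where a value is absent.
    """

    values: np.ndarray
    variable_names: list[str]
    variable_kinds: list[str]
    missing_mask: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if self.missing_mask.shape != (n, p):
            raise ValueError("missing_mask shape disagrees with values")
        if len(self.variable_names) != p:
            raise ValueError("variable_names length disagrees with values")
        if len(self.variable_kinds) != p:
            raise ValueError("variable_kinds length disagrees with values")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length disagrees with values")
        if len(set(self.variable_names)) != p:
            raise ValueError("duplicate variable names")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        for k in self.variable_kinds:
            if k not in KINDS:
                raise ValueError(f"unknown variable kind {k!r}")
        nan_mask = np.isnan(self.values)
        if not np.array_equal(nan_mask, self.missing_mask):
            raise ValueError("missing_mask must flag exactly the NaN cells")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def select_variables(self, names: Sequence[str]) -> "CohortTable":
        idx = [self.variable_names.index(n) for n in names]
        return CohortTable(
            values=self.values[:, idx].copy(),
            variable_names=[self.variable_names[i] for i in idx],
            variable_kinds=[self.variable_kinds[i] for i in idx],
            missing_mask=self.missing_mask[:, idx].copy(),
            subject_ids=list(self.subject_ids),
        )

    def select_subjects(self, index: Sequence[int] | np.ndarray) -> "CohortTable":
        index = np.asarray(index)
        ids = np.asarray(self.subject_ids, dtype=object)[index]
        # Bootstrap resamples repeat subjects; disambiguate repeated ids.
        seen: dict[str, int] = {}
        uniq = []
        for s in ids:
            c = seen.get(s, 0)
            seen[s] = c + 1
            uniq.append(s if c == 0 else f"{s}#{c}")
        return CohortTable(
            values=self.values[index].copy(),
            variable_names=list(self.variable_names),
            variable_kinds=list(self.variable_kinds),
            missing_mask=self.missing_mask[index].copy(),
            subject_ids=uniq,
        )

    def copy(self) -> "CohortTable":
        return replace(
            self,
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            variable_names=list(self.variable_names),
            variable_kinds=list(self.variable_kinds),
            subject_ids=list(self.subject_ids),
        )


@dataclass
class TargetVector:
    """Binary outcome aligned to the cohort's subjects (1 = case)."""

    labels: np.ndarray
    cutoff: float | None = None
    raw_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if self.raw_scores is not None:
            self.raw_scores = np.asarray(self.raw_scores, dtype=float)
            if self.raw_scores.shape != self.labels.shape:
                raise ValueError("raw_scores length disagrees with labels")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def subset(self, index: Sequence[int] | np.ndarray) -> "TargetVector":
        index = np.asarray(index)
        return TargetVector(
            labels=self.labels[index],
            cutoff=self.cutoff,
            raw_scores=None if self.raw_scores is None else self.raw_scores[index],
        )


def infer_kinds(values: np.ndarray, max_categorical_levels: int = 10) -> list[str]:
    """Infer variable kinds from observed values.

    <=2 distinct observed values -> binary; integer-valued with up to
    ``max_categorical_levels`` levels -> categorical; otherwise continuous.
    """
    kinds = []
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        levels = np.unique(obs)
        if levels.size <= 2:
            kinds.append("binary")
        elif levels.size <= max_categorical_levels and np.allclose(
            levels, np.round(levels)
        ):
            kinds.append("categorical")
        else:
            kinds.append("continuous")
    return kinds


def read_cohort(
    path: str | Path,
    delimiter: str = "\t",
    na_values: Iterable[str] = DEFAULT_NA_VALUES,
    id_column: str | None = None,
    kind_overrides: dict[str, str] | None = None,
) -> CohortTable:
    """Read a delimited cohort file with a header row of variable names.

    Empty cells and the configured sentinel strings are flagged missing.
    Duplicate column names and ragged rows are hard errors.
    """
    path = Path(path)
    na_set = set(na_values)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"{path}: duplicate column names {dupes}")
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: line {lineno} has {len(row)} fields, "
                    f"expected {len(header)}"
                )
            rows.append(row)

    id_idx = None
    if id_column is not None:
        if id_column not in header:
            raise ValueError(f"{path}: id column {id_column!r} not in header")
        id_idx = header.index(id_column)
        subject_ids = [r[id_idx].strip() for r in rows]
        names = [h for i, h in enumerate(header) if i != id_idx]
    else:
        subject_ids = [f"S{i + 1:04d}" for i in range(len(rows))]
        names = header

    values = np.empty((len(rows), len(names)), dtype=float)
    for i, row in enumerate(rows):
        cells = [c for k, c in enumerate(row) if k != id_idx]
        for j, cell in enumerate(cells):
            cell = cell.strip()
            if cell in na_set:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} in column "
                        f"{names[j]!r}, line {i + 2}"
                    ) from None

    kinds = infer_kinds(values)
    if kind_overrides:
        for name, kind in kind_overrides.items():
            if name in names:
                if kind not in KINDS:
                    raise ValueError(f"unknown kind override {kind!r}")
                kinds[names.index(name)] = kind

    table = CohortTable(
        values=values,
        variable_names=names,
        variable_kinds=kinds,
        missing_mask=np.isnan(values),
        subject_ids=subject_ids,
    )
    log.info(
        "read %s: %d subjects, %d variables, %d missing cells",
        path,
        table.n_subjects,
        table.n_variables,
        int(table.missing_mask.sum()),
    )
    return table


def write_cohort(table: CohortTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write a cohort table; missing cells become empty fields."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(table.variable_names)
        for i in range(table.n_subjects):
            row = []
            for j in range(table.n_variables):
                v = table.values[i, j]
                # repr is the shortest exactly round-tripping decimal form
                row.append("" if np.isnan(v) else repr(float(v)))
            writer.writerow(row)


def binarize_target(
    raw_scores: np.ndarray | Sequence[float], cutoff: float = DEFAULT_CUTOFF
) -> TargetVector:
    """Dichotomise outcome scores: label 1 iff score >= cutoff (inclusive)."""
    raw_scores = np.asarray(raw_scores, dtype=float)
    if np.isnan(raw_scores).any():
        raise ValueError("missing outcome scores; drop those subjects first")
    labels = (raw_scores >= cutoff).astype(int)
    if labels.min() == labels.max():
        warnings.warn(
            "binarize_target produced a single class; AUC will be undefined",
            stacklevel=2,
        )
    return TargetVector(labels=labels, cutoff=cutoff, raw_scores=raw_scores)


def extract_target(
    table: CohortTable, outcome_column: str, cutoff: float = DEFAULT_CUTOFF
) -> tuple[CohortTable, TargetVector]:
    """Split the outcome column off a cohort table and binarise it.

    Subjects with a missing outcome are dropped (the target cannot be
    imputed); the number dropped is logged.
    """
    scores = table.column(outcome_column)
    keep = ~np.isnan(scores)
    if (~keep).any():
        log.info("dropping %d subjects with missing outcome", int((~keep).sum()))
    predictors = [n for n in table.variable_names if n != outcome_column]
    table = table.select_subjects(np.flatnonzero(keep)).select_variables(predictors)
    return table, binarize_target(scores[keep], cutoff)


def load_sidecar_config(path: str | Path) -> dict:
    """Load the YAML sidecar config (outcome column, cutoff, kind overrides)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: sidecar config must be a mapping")
    return cfg
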