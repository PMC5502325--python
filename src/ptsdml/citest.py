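"""Conditional-independence and association tests on mixed-type data.

Two test families power the local causal discovery:

* G^2 likelihood-ratio test on contingency tables for all-discrete triples
  (x, y | Z), asymptotically chi-square with (|x|-1)(|y|-1)*prod|z| dof;
* Fisher z-test on the partial correlation of x and y given Z for anything
  involving a continuous variable (discrete variables entered numerically).

Each result carries a ``reliable`` flag from a sample-size heuristic; an
unreliable test never rejects independence, the standard guard against
spurious eliminations in constraint-based discovery at small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import CohortTable, TargetVector

DEFAULT_ALPHA = 0.05


@dataclass
class CITResult:
    statistic: float
    p_value: float
    dof: int
    test_name: str
    conditioning_set: list[str] = field(default_factory=list)
    reliable: bool = True

    def independent(self, alpha: float = DEFAULT_ALPHA) -> bool:
        """Independence is declared when p > alpha or the test is unreliable."""
        return (not self.reliable) or self.p_value > alpha


def g2_statistic(counts: np.ndarray) -> tuple[float, int]:
    """G^2 = 2 sum O ln(O/E) over an (x, y, strata) contingency array.

    ``counts`` has shape (levels_x, levels_y, n_strata); expected counts are
    computed per stratum from its margins.  Degrees of freedom are
    (|x|-1)(|y|-1) per stratum, summed over strata.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 2:
        counts = counts[:, :, None]
    rx, ry, ns = counts.shape
    g2 = 0.0
    dof = 0
    for s in range(ns):
        tab = counts[:, :, s]
        tot = tab.sum()
        dof += (rx - 1) * (ry - 1)
        if tot == 0:
            continue
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tot
        obs = tab > 0
        g2 += 2.0 * float(np.sum(tab[obs] * np.log(tab[obs] / expected[obs])))
    return g2, dof


def _encode_levels(col: np.ndarray) -> tuple[np.ndarray, int]:
    levels, codes = np.unique(col, return_inverse=True)
    return codes, len(levels)


def g2_test(
    x: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    min_expected: float = 5.0,
) -> tuple[float, float, int, bool]:
    """G^2 conditional-independence test of x against y given columns Z.

    Returns (statistic, p_value, dof, reliable).  The reliability heuristic
    requires the average expected cell count n / (|x||y|prod|z|) >= min_expected.
    """
    xc, rx = _encode_levels(x)
    yc, ry = _encode_levels(y)
    n = x.shape[0]
    if Z is None or Z.size == 0:
        strata = np.zeros(n, dtype=int)
        ns = 1
    else:
        Z = np.atleast_2d(Z.T).T  # (n, k)
        zc = np.zeros(n, dtype=int)
        ns = 1
        for j in range(Z.shape[1]):
            cj, rj = _encode_levels(Z[:, j])
            zc = zc * rj + cj
            ns *= rj
        strata = zc
    counts = np.zeros((rx, ry, ns))
    np.add.at(counts, (xc, yc, strata), 1.0)
    g2, dof = g2_statistic(counts)
    if dof <= 0:
        return 0.0, 1.0, 0, False
    p = float(stats.chi2.sf(g2, dof))
    reliable = (n / (rx * ry * ns)) >= min_expected
    return g2, p, dof, reliable


def fisher_z_test(
    x: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    min_effective_n: int = 10,
) -> tuple[float, float, int, bool]:
    """Fisher z-test of the partial correlation of x and y given Z.

    Returns (statistic, p_value, effective_n, reliable) where the statistic
    is sqrt(n - |Z| - 3) * atanh(r).  Zero-variance inputs give p = 1,
    unreliable.
    """
    n = x.shape[0]
    k = 0 if Z is None or Z.size == 0 else np.atleast_2d(Z.T).T.shape[1]
    eff = n - k - 3
    if eff < 1:
        return 0.0, 1.0, max(eff, 0), False
    if k:
        Zc = np.column_stack([np.ones(n), np.atleast_2d(Z.T).T])
        coef_x, *_ = np.linalg.lstsq(Zc, x, rcond=None)
        coef_y, *_ = np.linalg.lstsq(Zc, y, rcond=None)
        rx = x - Zc @ coef_x
        ry = y - Zc @ coef_y
    else:
        rx = x - x.mean()
        ry = y - y.mean()
    sx = float(np.sqrt(rx @ rx))
    sy = float(np.sqrt(ry @ ry))
    if sx < 1e-12 or sy < 1e-12:
        return 0.0, 1.0, eff, False
    r = float(np.clip((rx @ ry) / (sx * sy), -1 + 1e-15, 1 - 1e-15))
    z = np.arctanh(r)
    statistic = float(np.sqrt(eff) * z)
    p = float(2.0 * stats.norm.sf(abs(statistic)))
    reliable = eff >= min_effective_n
    return statistic, p, eff, reliable


class CITester:
    """Conditional-independence tester bound to a complete data matrix.

    ``X`` holds all variables as columns (the target may be one of them);
    ``kinds`` gives each column's kind.  Dispatch: all-discrete triples use
    the G^2 test, anything involving a continuous variable the Fisher z-test;
    ``method`` can force 'fisher_z' (discrete entered numerically) or 'g2'
    (continuous variables median-discretised).
    """

    def __init__(
        self,
        X: np.ndarray,
        kinds: Sequence[str],
        names: Sequence[str] | None = None,
        alpha: float = DEFAULT_ALPHA,
        method: str = "auto",
        max_cond: int | None = None,
        min_expected: float = 5.0,
        min_effective_n: int = 10,
    ):
        if method not in ("auto", "fisher_z", "g2"):
            raise ValueError(f"unknown CI test method {method!r}")
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("CI tests require complete data (impute first)")
        self.X = X
        self.kinds = list(kinds)
        self.names = list(names) if names is not None else [
            f"V{j}" for j in range(X.shape[1])
        ]
        self.alpha = alpha
        self.method = method
        self.max_cond = max_cond
        self.min_expected = min_expected
        self.min_effective_n = min_effective_n
        self.n_tests = 0
        if method == "g2":
            self._discretised = X.copy()
            for j, kind in enumerate(self.kinds):
                if kind == "continuous":
                    self._discretised[:, j] = (
                        X[:, j] > np.median(X[:, j])
                    ).astype(float)
        else:
            self._discretised = None

    def _is_discrete(self, j: int) -> bool:
        return self.kinds[j] in ("binary", "categorical")

    def test(self, i: int, j: int, cond: Sequence[int] = ()) -> CITResult:
        cond = tuple(cond)
        if i == j or i in cond or j in cond:
            raise ValueError("x, y and Z must be distinct")
        if self.max_cond is not None and len(cond) > self.max_cond:
            raise ValueError(
                f"conditioning set of size {len(cond)} exceeds max {self.max_cond}"
            )
        self.n_tests += 1
        cset = [self.names[c] for c in cond]
        use_g2 = self.method == "g2" or (
            self.method == "auto"
            and self._is_discrete(i)
            and self._is_discrete(j)
            and all(self._is_discrete(c) for c in cond)
        )
        X = self._discretised if self.method == "g2" else self.X
        Z = X[:, list(cond)] if cond else None
        if use_g2:
            stat, p, dof, reliable = g2_test(
                X[:, i], X[:, j], Z, min_expected=self.min_expected
            )
            return CITResult(stat, p, dof, "g2", cset, reliable)
        stat, p, eff, reliable = fisher_z_test(
            self.X[:, i], self.X[:, j],
            self.X[:, list(cond)] if cond else None,
            min_effective_n=self.min_effective_n,
        )
        return CITResult(stat, p, eff, "fisher_z", cset, reliable)


def make_tester(
    table: CohortTable,
    target: TargetVector,
    alpha: float = DEFAULT_ALPHA,
    method: str = "auto",
    max_cond: int | None = None,
    **kwargs,
) -> tuple[CITester, int]:
    """Build a CITester over [predictors | target]; returns it and the
    target's column index."""
    X = np.column_stack([table.values, target.labels.astype(float)])
    kinds = list(table.variable_kinds) + ["binary"]
    names = list(table.variable_names) + ["__target__"]
    tester = CITester(
        X, kinds, names, alpha=alpha, method=method, max_cond=max_cond, **kwargs
    )
    return tester, X.shape[1] - 1


def test_ci(
    x: str,
    y: str,
    Z: Sequence[str],
    table: CohortTable,
    alpha: float = DEFAULT_ALPHA,
    method: str = "auto",
    **kwargs,
) -> CITResult:
    """Name-based conditional-independence test on a complete cohort table."""
    idx = {n: j for j, n in enumerate(table.variable_names)}
    tester = CITester(
        table.values, table.variable_kinds, table.variable_names,
        alpha=alpha, method=method, **kwargs,
    )
    return tester.test(idx[x], idx[y], [idx[z] for z in Z])


def association_rank(
    target: TargetVector,
    table: CohortTable,
    alpha: float = DEFAULT_ALPHA,
    method: str = "auto",
    **kwargs,
) -> list[tuple[str, float]]:
    """Unconditionally associated variables, strongest first.

    Variables with univariate p <= alpha, sorted by ascending p, then by
    descending |statistic|, then variable name (a deterministic tie-break).
    """
    tester, t_idx = make_tester(table, target, alpha=alpha, method=method, **kwargs)
    ranked = []
    for j, name in enumerate(table.variable_names):
        res = tester.test(j, t_idx)
        if res.reliable and res.p_value <= alpha:
            ranked.append((name, res.p_value, abs(res.statistic)))
    ranked.sort(key=lambda t: (t[1], -t[2], t[0]))
    return [(name, p) for name, p, _ in ranked]
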