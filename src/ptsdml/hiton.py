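"""Semi-interleaved HITON-PC without symmetry correction.

Estimates the parents-and-children (PC) set of a binary target: candidates
enter in order of univariate association strength, and each newly admitted
candidate is immediately challenged by conditional-independence tests against
every subset (up to ``max_k``) of the variables admitted so far; a final
backward pass re-challenges every survivor.  When the target is terminal
(no children, hence no spouses) the PC set coincides with the Markov
boundary — the minimal maximally predictive variable set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from .citest import DEFAULT_ALPHA, CITester, make_tester
from .cohort import CohortTable, TargetVector

log = logging.getLogger(__name__)


@dataclass
class PCSet:
    """Result of a HITON-PC run.

    ``eliminated`` records, for each discarded variable, the witness
    conditioning set (variable names) that rendered it independent of the
    target.
    """

    selected: list[str]
    admission_order: list[str]
    eliminated: list[tuple[str, tuple[str, ...]]]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sel = set(self.selected)
        if sel & {name for name, _ in self.eliminated}:
            raise ValueError("a variable is both selected and eliminated")

    def __contains__(self, name: str) -> bool:
        return name in self.selected

    def __len__(self) -> int:
        return len(self.selected)


def _first_separating_subset(
    tester: CITester,
    cand: int,
    t_idx: int,
    pool: Sequence[int],
    max_k: int,
    alpha: float,
) -> tuple[int, ...] | None:
    """Smallest-first search for a subset of ``pool`` separating cand from T.

    Subsets are enumerated in increasing size and, within a size, in the
    pool's (admission) order, so the earliest/cheapest witness is recorded.
    """
    for size in range(1, min(max_k, len(pool)) + 1):
        for subset in combinations(pool, size):
            res = tester.test(cand, t_idx, subset)
            if res.independent(alpha):
                return subset
    return None


def run_hiton_pc(
    target: TargetVector,
    table: CohortTable,
    alpha: float = DEFAULT_ALPHA,
    max_k: int = 3,
    ci_test: str = "auto",
    **tester_kwargs,
) -> PCSet:
    """Run semi-interleaved HITON-PC for the target on a complete table.

    1. Open list: variables unconditionally associated with the target
       (p <= alpha), strongest association first.
    2. Interleaved elimination: pop the best candidate into the tentative PC
       set (TPC); test it against the target conditioned on every subset of
       the previously admitted variables of size <= max_k; the first
       separating subset discards it permanently.
    3. Backward pass: each TPC member is re-tested against subsets of the
       other current members; separated members are removed.
    No symmetry (AND) correction is applied.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    tester, t_idx = make_tester(
        table, target, alpha=alpha, method=ci_test, max_cond=max_k, **tester_kwargs
    )
    idx = {n: j for j, n in enumerate(table.variable_names)}

    from .citest import association_rank  # local import avoids cycle at module load

    open_list = association_rank(target, table, alpha=alpha, method=ci_test,
                                 **tester_kwargs)
    tpc: list[int] = []
    admission_order: list[str] = []
    eliminated: list[tuple[str, tuple[str, ...]]] = []

    for name, _p in open_list:
        cand = idx[name]
        witness = _first_separating_subset(tester, cand, t_idx, tpc, max_k, alpha)
        if witness is None:
            tpc.append(cand)
            admission_order.append(name)
        else:
            eliminated.append(
                (name, tuple(table.variable_names[j] for j in witness))
            )

    # final backward pass over the tentative PC set
    for cand in list(tpc):
        others = [j for j in tpc if j != cand]
        witness = _first_separating_subset(tester, cand, t_idx, others, max_k, alpha)
        if witness is not None:
            tpc.remove(cand)
            eliminated.append(
                (
                    table.variable_names[cand],
                    tuple(table.variable_names[j] for j in witness),
                )
            )

    selected = [table.variable_names[j] for j in tpc]
    log.info(
        "HITON-PC: %d candidates, %d selected, %d eliminated (%d CI tests)",
        len(open_list), len(selected), len(eliminated), tester.n_tests,
    )
    return PCSet(
        selected=selected,
        admission_order=admission_order,
        eliminated=eliminated,
        params={"alpha": alpha, "max_k": max_k, "ci_test": ci_test},
    )


def select_within_fold(
    train_table: CohortTable,
    train_target: TargetVector,
    alpha: float = DEFAULT_ALPHA,
    max_k: int = 3,
    ci_test: str = "auto",
    **tester_kwargs,
) -> PCSet:
    """HITON-PC scoped to a training fold (no test-fold subject involved)."""
    if train_target.n_positive < 2:
        warnings.warn(
            "training fold has fewer than 2 positive subjects; "
            "selection proceeds but is fragile",
            stacklevel=2,
        )
    return run_hiton_pc(
        train_target, train_table, alpha=alpha, max_k=max_k, ci_test=ci_test,
        **tester_kwargs,
    )
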