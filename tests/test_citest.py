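"""Conditional-independence test primitives."""

import numpy as np
import pytest
from scipy import stats

from ptsdml.citest import (
    CITester,
    association_rank,
    fisher_z_test,
    g2_statistic,
    g2_test,
    test_ci as ci_test_by_name,
)
from ptsdml.cohort import TargetVector

from conftest import make_table


def brute_force_g2(counts):
    """Independent oracle: explicit loop over cells and strata."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 2:
        counts = counts[:, :, None]
    g2 = 0.0
    for s in range(counts.shape[2]):
        tab = counts[:, :, s]
        tot = tab.sum()
        if tot == 0:
            continue
        for i in range(tab.shape[0]):
            for j in range(tab.shape[1]):
                o = tab[i, j]
                if o > 0:
                    e = tab[i, :].sum() * tab[:, j].sum() / tot
                    g2 += 2.0 * o * np.log(o / e)
    return g2


class TestG2:
    def test_hand_computed_2x2(self):
        # expected counts are all 15; G2 = 2*sum O ln(O/E) ~= 6.796
        g2, dof = g2_statistic(np.array([[20.0, 10.0], [10.0, 20.0]]))
        assert g2 == pytest.approx(6.796, abs=1e-3)
        assert dof == 1
        assert stats.chi2.sf(g2, dof) == pytest.approx(0.0091, abs=2e-4)

    def test_matches_brute_force_enumeration(self, rng):
        # random small 2x2 and 2x2x2 tables with cell counts <= 5
        for _ in range(300):
            shape = (2, 2) if rng.random() < 0.5 else (2, 2, 2)
            counts = rng.integers(0, 6, size=shape).astype(float)
            g2, _ = g2_statistic(counts)
            assert g2 == pytest.approx(brute_force_g2(counts), abs=1e-9)

    def test_conditional_independence_detected(self, rng):
        # x -> z -> y: dependent marginally, independent given z
        n = 4000
        z = rng.binomial(1, 0.5, n)
        x = np.where(rng.random(n) < 0.8, z, 1 - z)
        y = np.where(rng.random(n) < 0.8, z, 1 - z)
        _, p_marg, _, _ = g2_test(x, y)
        _, p_cond, _, _ = g2_test(x, y, z.reshape(-1, 1).astype(float))
        assert p_marg < 1e-6
        assert p_cond > 0.01


class TestFisherZ:
    def test_self_dependence(self, rng):
        x = rng.standard_normal(200)
        _, p, _, _ = fisher_z_test(x, x)
        assert p < 1e-6

    def test_partial_correlation_removes_common_cause(self, rng):
        n = 3000
        z = rng.standard_normal(n)
        x = z + 0.5 * rng.standard_normal(n)
        y = z + 0.5 * rng.standard_normal(n)
        _, p_marg, _, _ = fisher_z_test(x, y)
        _, p_cond, _, _ = fisher_z_test(x, y, z.reshape(-1, 1))
        assert p_marg < 1e-10
        assert p_cond > 0.01

    def test_type_one_error_and_uniformity(self, rng):
        # under independence the p-value is approximately Uniform(0,1)
        pvals = []
        for _ in range(500):
            x = rng.standard_normal(1000)
            y = rng.standard_normal(1000)
            _, p, _, _ = fisher_z_test(x, y)
            pvals.append(p)
        pvals = np.asarray(pvals)
        rate = float(np.mean(pvals <= 0.05))
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(rate - 0.05) < 3 * se + 1e-9
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_is_unreliable(self, rng):
        x = np.ones(50)
        y = rng.standard_normal(50)
        stat, p, _, reliable = fisher_z_test(x, y)
        assert p == 1.0 and not reliable


class TestCITester:
    def test_symmetry_in_x_and_y(self, rng):
        X = rng.standard_normal((120, 4))
        tester = CITester(X, ["continuous"] * 4)
        a = tester.test(0, 1, (2, 3))
        b = tester.test(1, 0, (2, 3))
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_dispatch_by_kind(self, rng):
        X = np.column_stack(
            [rng.binomial(1, 0.5, 300), rng.binomial(1, 0.5, 300),
             rng.standard_normal(300)]
        )
        tester = CITester(X, ["binary", "binary", "continuous"])
        assert tester.test(0, 1).test_name == "g2"
        assert tester.test(0, 2).test_name == "fisher_z"

    def test_max_cond_enforced(self, rng):
        X = rng.standard_normal((100, 5))
        tester = CITester(X, ["continuous"] * 5, max_cond=1)
        with pytest.raises(ValueError, match="exceeds"):
            tester.test(0, 1, (2, 3))

    def test_unreliable_never_rejects(self, rng):
        # 10 subjects, conditioning on 3: effective n too small
        X = rng.standard_normal((10, 5))
        tester = CITester(X, ["continuous"] * 5)
        res = tester.test(0, 1, (2, 3, 4))
        assert not res.reliable
        assert res.independent(alpha=0.05)

    def test_name_based_interface(self, rng):
        table = make_table(rng.standard_normal((100, 3)), names=["x", "y", "z"])
        res = ci_test_by_name("x", "y", ["z"], table)
        assert res.conditioning_set == ["z"]


class TestAssociationRank:
    def test_planted_parent_ranked_first(self, rng):
        n = 1000
        x = rng.standard_normal((n, 10))
        y = (x[:, 7] + 0.5 * rng.standard_normal(n) > 1.0).astype(int)
        table = make_table(x)
        ranked = association_rank(TargetVector(y), table)
        assert ranked[0][0] == "v7"

    def test_null_admission_rate_near_alpha(self, rng):
        admitted = []
        for _ in range(40):
            table = make_table(rng.standard_normal((200, 25)))
            y = TargetVector(rng.binomial(1, 0.3, 200))
            admitted.append(len(association_rank(y, table, alpha=0.05)))
        mean_rate = np.mean(admitted) / 25
        assert 0.01 < mean_rate < 0.10

    def test_empty_table(self, rng):
        table = make_table(np.empty((50, 0)))
        y = TargetVector(rng.binomial(1, 0.5, 50))
        assert association_rank(y, table) == []
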