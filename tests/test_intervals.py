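import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    Z95,
    agresti_caffo_oracle,
    loglik,
    newcombe_oracle,
    score_grid_ci,
    wald_oracle,
)
from rdci.intervals import (
    METHODS,
    ArmCount,
    Interval,
    TwoArmTable,
    agresti_caffo_ci,
    compute_all,
    mn_ci,
    mn_score_statistic,
    newcombe_ci,
    restricted_mle,
    scas_ci,
    wald_ci,
    wilson_ci,
)

# hypothesis strategy for small random tables
arm = st.integers(min_value=1, max_value=60).flatmap(
    lambda n: st.tuples(st.integers(min_value=0, max_value=n), st.just(n))
)
tables = st.tuples(arm, arm).map(
    lambda t: TwoArmTable(ArmCount(*t[0]), ArmCount(*t[1]))
)


class TestTypes:
    def test_arm_count_invariants(self):
        with pytest.raises(ValueError):
            ArmCount(-1, 10)
        with pytest.raises(ValueError):
            ArmCount(11, 10)
        with pytest.raises(ValueError):
            ArmCount(0, 0)
        assert ArmCount(3, 10).rate == 0.3
        assert ArmCount(3, 10).failures == 7

    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            Interval(0.5, 0.2, 0.95, "wald")
        with pytest.raises(ValueError):
            Interval(0.0, 0.1, 1.5, "wald")
        assert Interval(-0.1, 0.3, 0.95, "wald").width == pytest.approx(0.4)

    def test_estimate(self, micro_table):
        assert micro_table.estimate == pytest.approx(0.2)


class TestWald:
    def test_worked_example(self, micro_table):
        iv = wald_ci(micro_table)
        assert (round(iv.lower, 3), round(iv.upper, 3)) == (-0.192, 0.592)

    def test_degenerate_zero_width(self, degenerate_table):
        iv = wald_ci(degenerate_table)
        assert iv.lower == iv.upper == 0.0

    def test_swap_antisymmetry(self, micro_table):
        a = wald_ci(micro_table)
        b = wald_ci(micro_table.swapped())
        assert a.lower == pytest.approx(-b.upper, abs=1e-15)
        assert a.upper == pytest.approx(-b.lower, abs=1e-15)

    def test_inverse_sqrt_n_scaling(self):
        base = TwoArmTable(ArmCount(8, 10), ArmCount(6, 10))
        big = TwoArmTable(ArmCount(32, 40), ArmCount(24, 40))
        assert wald_ci(big).width == pytest.approx(wald_ci(base).width / 2, abs=1e-12)


class TestAgrestiCaffo:
    def test_worked_example(self, micro_table):
        iv = agresti_caffo_ci(micro_table)
        assert (round(iv.lower, 3), round(iv.upper, 3)) == (-0.205, 0.538)

    @given(tables)
    @settings(max_examples=50, deadline=None)
    def test_equals_wald_on_augmented(self, table):
        a = agresti_caffo_ci(table)
        w = wald_ci(table.augmented())
        assert (a.lower, a.upper) == (w.lower, w.upper)

    def test_zero_counts_nonzero_width(self):
        iv = agresti_caffo_ci(TwoArmTable(ArmCount(0, 10), ArmCount(0, 10)))
        assert iv.width > 0
        assert iv.lower == pytest.approx(-iv.upper)


class TestWilson:
    def test_worked_example(self):
        iv = wilson_ci(ArmCount(8, 10))
        assert (round(iv.lower, 3), round(iv.upper, 3)) == (0.490, 0.943)

    def test_boundaries(self):
        assert wilson_ci(ArmCount(0, 15)).lower == 0.0
        assert wilson_ci(ArmCount(15, 15)).upper == 1.0

    @given(arm)
    @settings(max_examples=50, deadline=None)
    def test_complement_symmetry(self, xn):
        x, n = xn
        a = wilson_ci(ArmCount(x, n))
        b = wilson_ci(ArmCount(n - x, n))
        assert a.lower == pytest.approx(1 - b.upper, abs=1e-12)
        assert a.upper == pytest.approx(1 - b.lower, abs=1e-12)

    def test_contains_estimate(self):
        for x, n in [(0, 5), (3, 7), (7, 7), (1, 40)]:
            iv = wilson_ci(ArmCount(x, n))
            assert iv.lower <= x / n <= iv.upper


class TestNewcombe:
    def test_worked_example(self, micro_table):
        iv = newcombe_ci(micro_table)
        assert (round(iv.lower, 3), round(iv.upper, 3)) == (-0.187, 0.521)

    def test_equal_arms_symmetric(self):
        iv = newcombe_ci(TwoArmTable(ArmCount(7, 20), ArmCount(7, 20)))
        assert iv.lower == pytest.approx(-iv.upper, abs=1e-12)

    def test_contains_estimate(self, micro_table):
        iv = newcombe_ci(micro_table)
        assert iv.lower <= micro_table.estimate <= iv.upper


class TestRestrictedMLE:
    def test_unconstrained_at_dhat(self, micro_table):
        p1, p2 = restricted_mle(micro_table, micro_table.estimate)
        assert p1 == pytest.approx(0.8, abs=1e-9)
        assert p2 == pytest.approx(0.6, abs=1e-9)

    def test_likelihood_optimality_vs_grid(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1, n2 = (int(v) for v in rng.integers(2, 40, 2))
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            d = float(rng.uniform(-0.95, 0.95))
            table = TwoArmTable(ArmCount(x1, n1), ArmCount(x2, n2))
            p1, p2 = restricted_mle(table, d)
            best = loglik(x1, n1, x2, n2, p1, p2)
            grid = np.linspace(max(0.0, -d), min(1.0, 1.0 - d), 1001)
            ll = loglik(x1, n1, x2, n2, grid + d, grid)
            assert best >= np.nanmax(ll) - 1e-7

    def test_boundary_adjacent_no_raise(self):
        table = TwoArmTable(ArmCount(0, 10), ArmCount(10, 10))
        p1, p2 = restricted_mle(table, -0.999999)
        assert 0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0

    def test_constraint_satisfied(self, micro_table):
        for d in (-0.7, -0.2, 0.0, 0.3, 0.8):
            p1, p2 = restricted_mle(micro_table, d)
            assert p1 - p2 == pytest.approx(d, abs=1e-12)
            assert 0.0 <= p2 <= 1.0 and 0.0 <= p1 <= 1.0


class TestScoreStatistic:
    def test_zero_at_estimate(self, micro_table):
        assert mn_score_statistic(micro_table, micro_table.estimate) == 0.0

    def test_sign(self, micro_table):
        d = micro_table.estimate
        assert mn_score_statistic(micro_table, d - 0.1) > 0
        assert mn_score_statistic(micro_table, d + 0.1) < 0

    def test_matches_oracle_recomputation(self, micro_table):
        # recompute from scratch: constrained MLE by likelihood grid, then z
        for d in (-0.3, 0.0, 0.45):
            grid = np.linspace(max(0.0, -d), min(1.0, 1.0 - d), 2000001)
            ll = loglik(8, 10, 6, 10, grid + d, grid)
            p2 = float(grid[np.nanargmax(ll)])
            p1 = p2 + d
            v = (p1 * (1 - p1) / 10 + p2 * (1 - p2) / 10) * 20 / 19
            expected = (0.2 - d) / math.sqrt(v)
            assert mn_score_statistic(micro_table, d) == pytest.approx(
                expected, abs=1e-6
            )


class TestScoreIntervals:
    def test_mn_grid_oracle(self, micro_table):
        lo, hi = score_grid_ci(8, 10, 6, 10, skew=False)
        iv = mn_ci(micro_table)
        assert iv.lower == pytest.approx(lo, abs=1e-4)
        assert iv.upper == pytest.approx(hi, abs=1e-4)

    def test_scas_grid_oracle(self, micro_table):
        lo, hi = score_grid_ci(8, 10, 6, 10, skew=True)
        iv = scas_ci(micro_table)
        assert iv.lower == pytest.approx(lo, abs=1e-4)
        assert iv.upper == pytest.approx(hi, abs=1e-4)

    def test_mn_reference_example(self):
        # 56/70 vs 48/80: the widely reproduced reference interval for the
        # restricted-MLE score method with N/(N-1) inflation
        iv = mn_ci(TwoArmTable(ArmCount(56, 70), ArmCount(48, 80)))
        assert (round(iv.lower, 4), round(iv.upper, 4)) == (0.0528, 0.3382)

    def test_equal_arms_symmetric(self):
        table = TwoArmTable(ArmCount(12, 30), ArmCount(12, 30))
        for fn in (mn_ci, scas_ci):
            iv = fn(table)
            assert iv.lower == pytest.approx(-iv.upper, abs=1e-7)

    def test_boundary_upper_limit_is_one(self):
        iv = mn_ci(TwoArmTable(ArmCount(10, 10), ArmCount(0, 10)))
        assert iv.upper == 1.0

    def test_scas_reduces_to_mn_without_skewness(self, micro_table):
        tables = [
            micro_table,
            TwoArmTable(ArmCount(0, 10), ArmCount(3, 12)),
            TwoArmTable(ArmCount(19, 20), ArmCount(55, 60)),
        ]
        for table in tables:
            a = scas_ci(table, skewness=False)
            b = mn_ci(table)
            assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_score_residual_at_limits(self, micro_table):
        iv = mn_ci(micro_table)
        assert abs(mn_score_statistic(micro_table, iv.lower) - Z95) < 1e-5
        assert abs(mn_score_statistic(micro_table, iv.upper) + Z95) < 1e-5

    def test_estimate_strictly_inside(self, micro_table):
        for fn in (mn_ci, scas_ci):
            iv = fn(micro_table)
            assert iv.lower < micro_table.estimate < iv.upper


class TestComputeAll:
    def test_five_methods(self, micro_table):
        out = compute_all(micro_table)
        assert tuple(out) == METHODS
        expected = {
            "wald": (-0.192, 0.592),
            "agresti_caffo": (-0.205, 0.538),
            "newcombe": (-0.187, 0.521),
        }
        for m, (lo, hi) in expected.items():
            assert (round(out[m].lower, 3), round(out[m].upper, 3)) == (lo, hi)

    def test_degenerate_contrast(self, degenerate_table):
        out = compute_all(degenerate_table)
        assert out["wald"].width == 0.0
        for m in METHODS[1:]:
            assert out[m].width > 0


@given(tables)
@settings(max_examples=30, deadline=None)
def test_arm_swap_antisymmetry_all_methods(table):
    a = compute_all(table)
    b = compute_all(table.swapped())
    for m in METHODS:
        assert a[m].lower == pytest.approx(-b[m].upper, abs=1e-7)
        assert a[m].upper == pytest.approx(-b[m].lower, abs=1e-7)


@given(tables)
@settings(max_examples=15, deadline=None)
def test_level_monotonicity(table):
    for m in METHODS:
        widths = [compute_all(table, lvl)[m].width for lvl in (0.90, 0.95, 0.99)]
        assert widths[0] <= widths[1] + 1e-9 <= widths[2] + 2e-9


@given(tables)
@settings(max_examples=30, deadline=None)
def test_limits_within_unit_interval(table):
    for iv in compute_all(table).values():
        assert -1.0 <= iv.lower <= iv.upper <= 1.0


def test_closed_form_oracles_random_tables():
    rng = np.random.default_rng(7)
    from conftest import random_tables

    for table in random_tables(rng, 50):
        x1, n1 = table.treatment.successes, table.treatment.total
        x2, n2 = table.control.successes, table.control.total
        for fn, oracle in (
            (wald_ci, wald_oracle),
            (agresti_caffo_ci, agresti_caffo_oracle),
            (newcombe_ci, newcombe_oracle),
        ):
            iv = fn(table)
            lo, hi = oracle(x1, n1, x2, n2)
            assert iv.lower == pytest.approx(lo, abs=1e-6)
            assert iv.upper == pytest.approx(hi, abs=1e-6)
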