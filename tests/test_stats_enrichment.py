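import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from iddtools.stats_enrichment import (
    bh_adjust,
    enrich,
    fit_line,
    grade_matrix,
    hypergeom_tails,
    mann_whitney,
    signed_grade,
    spearman,
)


def exact_tails(k, K, n, N):
    """Oracle: exact integer-combinatorics tail sums."""
    denom = math.comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(n, K)
    pmf = {j: Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
           for j in range(lo, hi + 1)}
    p_over = float(sum(v for j, v in pmf.items() if j >= k))
    p_under = float(sum(v for j, v in pmf.items() if j <= k))
    return p_over, p_under


class TestHypergeom:
    def test_worked_example(self):
        # C(5,5)C(5,0)/C(10,5) = 1/252
        p_over, _ = hypergeom_tails(5, 5, 5, 10)
        assert p_over == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_hits(self):
        p_over, p_under = hypergeom_tails(0, 4, 3, 10)
        assert p_over == pytest.approx(1.0)
        assert p_under == pytest.approx(exact_tails(0, 4, 3, 10)[1], rel=1e-12)

    def test_degenerate_full_selection(self):
        p_over, p_under = hypergeom_tails(5, 5, 5, 5)
        assert p_over == pytest.approx(1.0) and p_under == pytest.approx(1.0)

    def test_bounds_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tails(6, 5, 5, 10)

    def test_random_grid_against_oracle(self, rng):
        for _ in range(300):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n - (N - K)), min(n, K) + 1))
            got = hypergeom_tails(k, K, n, N)
            want = exact_tails(k, K, n, N)
            assert got[0] == pytest.approx(want[0], rel=1e-9, abs=1e-12)
            assert got[1] == pytest.approx(want[1], rel=1e-9, abs=1e-12)

    def test_tails_share_point_mass(self, rng):
        for _ in range(100):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, n - (N - K)), min(n, K) + 1))
            p_over, p_under = hypergeom_tails(k, K, n, N)
            assert p_over + p_under >= 1.0 - 1e-12


class TestBH:
    def test_hand_worked_stepup(self):
        # 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_one(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    def test_monotone_in_rank(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200).clip(1e-12, 1.0)
        q = bh_adjust(p)
        q_sm = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, q_sm, rtol=1e-10)


class TestSignedGrade:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (1e-13, 7), (10 ** -12.0, 7), (10 ** -11.999, 6), (10 ** -9.0, 6),
            (10 ** -8.999, 5), (10 ** -6.0, 5), (10 ** -5.999, 4),
            (10 ** -3.0, 4), (10 ** -2.999, 3), (10 ** -2.0, 3),
            (10 ** -1.999, 2), (10 ** -1.301, 2), (0.05, 2),
            (10 ** -1.3, 0.25), (0.5, 0.25), (1.0, 0.25),
        ],
    )
    def test_over_side_bins(self, p, expected):
        assert signed_grade(p, 1.0) == expected

    @pytest.mark.parametrize("p,expected", [(1e-13, -7), (0.05, -2), (0.1, -0.25)])
    def test_under_side_bins(self, p, expected):
        assert signed_grade(1.0, p) == expected

    def test_symmetry(self):
        for p in (1e-13, 1e-7, 1e-3, 0.02, 0.3):
            assert signed_grade(p, 1.0) == -signed_grade(1.0, p)


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        down = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert up.rho == pytest.approx(1.0) and down.rho == pytest.approx(-1.0)

    def test_constant_flagged_undefined(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert not res.defined and np.isnan(res.rho)


def exhaustive_mw_p(x, y):
    """Oracle: exact two-sided Mann-Whitney P by enumerating all group
    assignments of the pooled sample (no ties)."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    m = len(y)
    mid = n * m / 2
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = mann_whitney([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p > 0.9

    def test_full_separation_u(self):
        u, _ = mann_whitney(list(range(10)), list(range(100, 110)))
        assert u == 0.0
        u2, _ = mann_whitney(list(range(100, 110)), list(range(10)))
        assert u2 == 100.0

    def test_exact_matches_permutation_oracle(self, rng):
        for _ in range(20):
            n, m = rng.integers(2, 9, size=2)
            pooled = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = pooled[:n], pooled[n:]
            _, p = mann_whitney(x, y, method="exact")
            assert p == pytest.approx(exhaustive_mw_p(x, y), rel=1e-9)


class TestFitLine:
    def test_collinear_recovered_exactly(self):
        slope, intercept = fit_line([0, 1, 2, 3], [5, 7, 9, 11])
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(5.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_line([1], [1])

    def test_planted_slope_recovered(self, rng):
        x = rng.uniform(0, 50, 60)
        y = 0.8 * x + 4 + rng.normal(0, 1.0, 60)
        slope, _ = fit_line(x, y)
        assert slope == pytest.approx(0.8, abs=0.1)


class TestEnrichDriver:
    def test_selection_equals_universe_all_near_zero_grades(self):
        ann = pd.DataFrame({"family_id": ["f1", "f2", "f3"],
                            "term": ["T1", "T1", "T2"]})
        res = enrich(["f1", "f2", "f3"], ["f1", "f2", "f3"], ann)
        assert all(abs(r.grade) == 0.25 for r in res)

    def test_empty_annotation(self):
        ann = pd.DataFrame(columns=["family_id", "term"])
        assert enrich(["f1"], ["f1"], ann) == []

    def test_deterministic_term_order(self):
        ann = pd.DataFrame({"family_id": ["f1", "f2"], "term": ["B", "A"]})
        res = enrich(["f1"], ["f1", "f2"], ann)
        assert [r.term for r in res] == ["A", "B"]

    def test_grade_matrix_shape(self):
        ann = pd.DataFrame({"family_id": ["f1", "f2"], "term": ["A", "B"]})
        res = enrich(["f1"], ["f1", "f2"], ann)
        mat = grade_matrix({"grp": res})
        assert list(mat.index) == ["A", "B"] and list(mat.columns) == ["grp"]

    def test_null_type_one_error_controlled(self):
        """With no planted signal the fraction of q < 0.05 discoveries stays
        at or below nominal (within 2 SE over replicates)."""
        rng = np.random.default_rng(99)
        n_terms, reps, fps, tests = 20, 300, 0, 0
        for _ in range(reps):
            fams = [f"f{i}" for i in range(100)]
            ann = pd.DataFrame(
                [{"family_id": f, "term": f"T{t}"}
                 for f in fams for t in rng.choice(n_terms, 3, replace=False)]
            )
            selection = list(rng.choice(fams, 30, replace=False))
            for r in enrich(selection, fams, ann):
                tests += 1
                if min(r.q_over, r.q_under) < 0.05:
                    fps += 1
        rate = fps / tests
        se = math.sqrt(0.05 * 0.95 / tests)
        assert rate <= 0.05 + 2 * se
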