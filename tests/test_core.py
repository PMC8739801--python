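"""Range fitting, out-of-range judging, ranking and batch selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erj.core import (
    EmbeddingRange,
    OutOfRangeProfile,
    SelectionConfig,
    fit_range,
    fit_ranges_by_class,
    judge,
    rank_pool,
    select_batch,
)
from erj.extractor import EmbeddingMatrix


def _matrix(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return EmbeddingMatrix(
        sample_ids=[f"{prefix}{i}" for i in range(values.shape[0])], values=values
    )


def oracle_range(values):
    """Scalar double-loop min/max, independent of the vectorized path."""
    n, d = values.shape
    lower = [min(values[i][j] for i in range(n)) for j in range(d)]
    upper = [max(values[i][j] for i in range(n)) for j in range(d)]
    return np.array(lower), np.array(upper)


def oracle_judge(lower, upper, values):
    """Scalar double-loop count/exceedance."""
    out = []
    for row in values:
        count, exc = 0, 0.0
        for j, x in enumerate(row):
            if x < lower[j]:
                count += 1
                exc += lower[j] - x
            elif x > upper[j]:
                count += 1
                exc += x - upper[j]
        out.append((count, exc))
    return out


class TestFitRange:
    def test_small_example_by_inspection(self):
        r = fit_range(_matrix([[0, 1], [2, 3], [1, 2]]))
        assert r.lower.tolist() == [0, 1]
        assert r.upper.tolist() == [2, 3]
        assert r.n_fit == 3

    def test_single_row_degenerate(self):
        r = fit_range(_matrix([[5, 5]]))
        assert r.lower.tolist() == r.upper.tolist() == [5, 5]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(100, 64))
        r = fit_range(_matrix(values))
        lo, hi = oracle_range(values)
        np.testing.assert_array_equal(r.lower, lo)
        np.testing.assert_array_equal(r.upper, hi)

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            fit_range(_matrix(np.empty((0, 3))))
        with pytest.raises(ValueError):
            _matrix([[np.nan, 0.0]])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 20), st.integers(1, 8))
    def test_row_order_invariance(self, seed, n, d):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(n, d))
        r1 = fit_range(_matrix(values))
        r2 = fit_range(_matrix(values[::-1]))
        np.testing.assert_array_equal(r1.lower, r2.lower)
        np.testing.assert_array_equal(r1.upper, r2.upper)


class TestJudge:
    def test_interior_point_scores_zero(self):
        r = EmbeddingRange(lower=[0, 0], upper=[1, 1], n_fit=2)
        (p,) = judge(r, _matrix([[0.5, 0.5]]))
        assert p.count == 0 and p.exceedance == 0.0

    def test_single_violated_bound(self):
        r = EmbeddingRange(lower=[0, 0], upper=[1, 1], n_fit=2)
        (p,) = judge(r, _matrix([[2.0, 0.5]]))
        assert p.count == 1
        assert p.exceedance == pytest.approx(1.0)

    def test_boundary_values_are_inside(self):
        r = EmbeddingRange(lower=[0, 0], upper=[1, 1], n_fit=2)
        (p,) = judge(r, _matrix([[0.0, 1.0]]))
        assert p.count == 0

    def test_fit_samples_self_consistent(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(50, 10))
        m = _matrix(values)
        r = fit_range(m)
        assert all(p.count == 0 for p in judge(r, m))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(30, 12))
        pool = rng.normal(scale=2.0, size=(200, 12))
        r = fit_range(_matrix(base))
        profiles = judge(r, _matrix(pool, prefix="p"))
        expected = oracle_judge(r.lower, r.upper, pool)
        for p, (c, e) in zip(profiles, expected):
            assert p.count == c
            assert p.exceedance == pytest.approx(e)

    def test_dimension_mismatch_names_both_dims(self):
        r = EmbeddingRange(lower=[0], upper=[1], n_fit=1)
        with pytest.raises(ValueError, match="1"):
            judge(r, _matrix([[0.0, 1.0]]))

    def test_count_zero_iff_exceedance_zero(self):
        rng = np.random.default_rng(3)
        r = fit_range(_matrix(rng.normal(size=(10, 6))))
        for p in judge(r, _matrix(rng.normal(scale=3, size=(100, 6)), "q")):
            assert (p.count == 0) == (p.exceedance == 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_under_base_growth(self, seed):
        """range(B) contains range(A) for A subset of B; counts shrink."""
        rng = np.random.default_rng(seed)
        d = int(rng.integers(1, 10))
        a = rng.normal(size=(int(rng.integers(1, 20)), d))
        extra = rng.normal(size=(int(rng.integers(1, 20)), d))
        b = np.concatenate([a, extra])
        ra, rb = fit_range(_matrix(a)), fit_range(_matrix(b))
        assert rb.contains(ra)
        pool = _matrix(rng.normal(scale=2, size=(25, d)), "p")
        for pa, pb in zip(judge(ra, pool), judge(rb, pool)):
            assert pb.count <= pa.count


class TestPerClassRanges:
    def test_one_range_per_class_fitted_on_own_rows(self):
        values = np.array([[0.0], [1.0], [10.0], [11.0]])
        m = _matrix(values)
        ranges = fit_ranges_by_class(m, [0, 0, 1, 1])
        assert ranges[0].lower[0] == 0.0 and ranges[0].upper[0] == 1.0
        assert ranges[1].lower[0] == 10.0 and ranges[1].upper[0] == 11.0


def _profiles(spec):
    """spec: {id: (count, exceedance)}"""
    return [
        OutOfRangeProfile(sample_id=k, count=c, exceedance=e)
        for k, (c, e) in spec.items()
    ]


class TestRankPool:
    def test_hard_first_descending_count(self):
        p = _profiles({"a": (3, 1.0), "b": (0, 0.0), "c": (5, 1.0)})
        assert rank_pool(p, SelectionConfig(strategy="hard_first")) == ["c", "a", "b"]

    def test_bad_data_ascending_zeros_first(self):
        p = _profiles({"a": (3, 1.0), "b": (0, 0.0), "c": (5, 1.0)})
        assert rank_pool(p, SelectionConfig(strategy="bad_data")) == ["b", "a", "c"]

    def test_tie_broken_by_exceedance(self):
        p = _profiles({"a": (2, 0.1), "b": (2, 0.9)})
        assert rank_pool(p, SelectionConfig(strategy="hard_first")) == ["b", "a"]

    def test_easy_first_nonzero_ascending_zeros_last(self):
        p = _profiles({"a": (0, 0.0), "b": (1, 0.5), "c": (4, 2.0)})
        assert rank_pool(p, SelectionConfig(strategy="easy_first")) == ["b", "c", "a"]

    def test_random_is_seeded_permutation(self):
        p = _profiles({k: (i, float(i)) for i, k in enumerate("abcdefgh")})
        r1 = rank_pool(p, SelectionConfig(strategy="random", seed=7))
        r2 = rank_pool(p, SelectionConfig(strategy="random", seed=7))
        r3 = rank_pool(p, SelectionConfig(strategy="random", seed=8))
        assert r1 == r2
        assert sorted(r1) == sorted("abcdefgh")
        assert r1 != r3  # overwhelmingly likely for 8 items

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(strategy="hardest")

    def test_bad_data_prefix_disjoint_from_hard_first_prefix(self):
        """With any nonzero counts, the two strategies pick different heads."""
        rng = np.random.default_rng(4)
        p = _profiles(
            {f"s{i}": (int(c), float(c)) for i, c in enumerate(rng.integers(0, 5, 40))}
        )
        k = 5
        hard = rank_pool(p, SelectionConfig(strategy="hard_first"))[:k]
        bad = rank_pool(p, SelectionConfig(strategy="bad_data"))[:k]
        assert not set(hard) & set(bad)


class TestSelectBatch:
    def test_quota_per_class(self):
        ranked = {"a": ["a1", "a2", "a3"], "b": ["b1", "b2", "b3"]}
        batch = select_batch(ranked, SelectionConfig(per_class_quota=2))
        assert batch.selected == {"a": ["a1", "a2"], "b": ["b1", "b2"]}
        assert batch.shortfall == {}

    def test_head_of_ranking(self):
        batch = select_batch({"only": ["x", "y"]}, SelectionConfig(per_class_quota=1))
        assert batch.ids == ["x"]

    def test_exhausted_class_reports_shortfall(self):
        batch = select_batch({"c": ["x", "y"]}, SelectionConfig(per_class_quota=3))
        assert batch.selected["c"] == ["x", "y"]
        assert batch.shortfall == {"c": 1}
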