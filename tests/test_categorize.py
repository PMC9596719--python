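"""Unit and property tests for the categorization search."""

import itertools
import math
from statistics import mean

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mixcat.categorize import (
    Categorization,
    SearchConfig,
    adaptive_categorize,
    apply_thresholds,
    exhaustive_categorize,
    f_test_log_pvalue,
    iter_boundary_placements,
    linear_search_step,
    loss,
    quantile_categorize,
)
from mixcat.errors import (
    DegeneratePartitionError,
    InfeasibleKError,
    NoCandidateError,
)


def brute_force_best(values, k):
    """Independent oracle: enumerate every contiguous partition of the sorted
    values (boundaries only between distinct neighbours) and return the
    minimum loss, computed with plain-Python sums of squares."""
    x = sorted(float(v) for v in values)
    n = len(x)
    gm = mean(x)
    best = None
    for combo in itertools.combinations(range(1, n), k - 1):
        if any(x[p - 1] == x[p] for p in combo):
            continue
        edges = (0,) + combo + (n,)
        groups = [x[a:b] for a, b in zip(edges, edges[1:])]
        within = sum(sum((v - mean(g)) ** 2 for v in g) for g in groups)
        between = sum(len(g) * (mean(g) - gm) ** 2 for g in groups)
        if between <= 0:
            continue
        lo = 0.0 if within == 0 else (within / (n - k)) / (between / (k - 1))
        if best is None or lo < best:
            best = lo
    return best


class TestLoss:
    def test_zero_within(self):
        lo, f, within, between = loss([1, 1, 2, 2], [0, 0, 1, 1], 2)
        assert within == 0.0
        assert lo == 0.0
        assert f == math.inf

    def test_matches_anova_oracle(self):
        lo, f, within, between = loss([1, 2, 3, 4, 10], [0, 0, 0, 0, 1], 2)
        assert lo == pytest.approx((5.0 / 3) / 45.0, rel=1e-12)
        ref = stats.f_oneway(np.array([1.0, 2, 3, 4]), np.array([10.0]))
        assert f == pytest.approx(ref.statistic, rel=1e-9)
        assert within == pytest.approx(5.0)
        assert between == pytest.approx(45.0)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegeneratePartitionError):
            loss([5, 5, 5, 5], [0, 0, 1, 1], 2)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            loss([1, 2, 3], [0, 0, 0], 1)  # k < 2
        with pytest.raises(ValueError):
            loss([1, 2], [0, 1], 2)  # n <= k
        with pytest.raises(ValueError):
            loss([1, 2, 3, 4], [0, 0, 0, 0], 2)  # empty category

    def test_conservation(self, rng):
        x = rng.normal(size=25)
        lab = np.sort(rng.integers(0, 3, size=25))
        lab[:3] = [0, 1, 2]  # ensure all categories occupied
        lab = np.sort(lab)
        _, _, within, between = loss(x, lab, 3)
        total = float(np.sum((x - x.mean()) ** 2))
        assert within + between == pytest.approx(total, rel=1e-9)


class TestExhaustive:
    def test_enumeration_count_16_2(self):
        # complexity formula: C(n-1, k-1) placements
        assert sum(1 for _ in iter_boundary_placements(16, 2)) == 15
        assert sum(1 for _ in iter_boundary_placements(16, 3)) == math.comb(15, 2)

    def test_outlier_split(self):
        c = exhaustive_categorize([1, 2, 3, 4, 10], 2)
        assert c.counts == (4, 1)
        assert c.loss == pytest.approx(brute_force_best([1, 2, 3, 4, 10], 2))
        assert list(c.labels) == [0, 0, 0, 0, 1]

    def test_three_exact_clusters(self):
        c = exhaustive_categorize([1, 1, 2, 2, 3, 3], 3)
        assert c.loss == 0.0
        assert c.counts == (2, 2, 2)
        assert list(c.labels) == [0, 0, 1, 1, 2, 2]

    def test_infeasible_k(self):
        with pytest.raises(InfeasibleKError):
            exhaustive_categorize([1, 1, 1, 2, 2, 2], 3)

    def test_n_cap(self):
        with pytest.raises(ValueError):
            exhaustive_categorize(np.arange(31.0), 2)

    @pytest.mark.parametrize("n,k", [(8, 2), (10, 3), (12, 2), (12, 3)])
    def test_oracle_equivalence(self, rng, n, k):
        for _ in range(20):
            x = np.round(rng.normal(size=n), 2)  # rounding creates ties
            if np.unique(x).size < k:
                continue
            c = exhaustive_categorize(x, k)
            assert c.loss == pytest.approx(brute_force_best(x, k), rel=1e-9, abs=1e-12)


def _manual_categorization(values, thresholds):
    """Build a k-category Categorization from given thresholds only
    (fields other than thresholds/k are irrelevant to the step search)."""
    labels = apply_thresholds(values, thresholds)
    k = len(thresholds) + 1
    return Categorization(
        thresholds=tuple(thresholds),
        k=k,
        labels=labels,
        counts=tuple(np.bincount(labels, minlength=k)),
        loss=float("nan"),
        f_statistic=float("nan"),
        p_value=float("nan"),
    )


class TestLinearSearchStep:
    def test_first_boundary_between_clusters(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)])
        start = _manual_categorization(x, [])
        c = linear_search_step(x, start)
        assert c.k == 2
        assert x[x <= c.thresholds[0]].max() < 1 < 4 < x[x > c.thresholds[0]].min()

    def test_keeps_previous_threshold(self):
        x = [1, 2, 3, 4, 10]
        c2 = exhaustive_categorize(x, 2)
        c3 = linear_search_step(x, c2)
        assert c3.k == 3
        assert c3.thresholds == (2.5, 7.0)
        # oracle: enumerate the 3 admissible inner boundaries of {1,2,3,4}
        candidates = []
        for t in (1.5, 2.5, 3.5):
            lab = apply_thresholds(x, [t, 7.0])
            candidates.append(loss(x, lab, 3)[0])
        assert c3.loss == pytest.approx(min(candidates), rel=1e-12)

    def test_bounded_below_by_exhaustive(self, rng):
        for _ in range(15):
            n = int(rng.integers(8, 21))
            x = np.round(rng.normal(size=n), 2)
            for k in (2, 3):
                if np.unique(x).size <= k:
                    continue
                ex_k = exhaustive_categorize(x, k)
                stepped = linear_search_step(x, exhaustive_categorize(x, k - 1)) \
                    if k > 2 else linear_search_step(x, _manual_categorization(x, []))
                assert stepped.loss >= ex_k.loss - 1e-12

    def test_no_candidate(self):
        x = np.array([1.0, 1.0, 2.0, 2.0])
        current = _manual_categorization(x, [1.5])
        with pytest.raises(NoCandidateError):
            linear_search_step(x, current)


class TestAdaptive:
    def test_three_clusters_selects_k3(self, three_cluster_values):
        c = adaptive_categorize(three_cluster_values)
        assert c.k == 3
        assert 0.0 <= c.p_value <= 1.0

    def test_k_fixed_contract(self, three_cluster_values):
        c = adaptive_categorize(three_cluster_values, SearchConfig(k_fixed=3))
        assert c.k == 3
        c2 = adaptive_categorize(three_cluster_values, SearchConfig(k_fixed=5))
        assert c2.k == 5

    def test_k_max_bound(self, rng):
        x = rng.uniform(size=400)
        c = adaptive_categorize(x)
        assert 2 <= c.k <= 10

    def test_constant_input(self):
        c = adaptive_categorize([3.0] * 10)
        assert c.k == 1
        assert c.degenerate
        assert math.isnan(c.loss)

    def test_min_fraction_enforced(self, rng):
        x = rng.lognormal(size=80)
        c = adaptive_categorize(
            x, SearchConfig(k_fixed=3, min_category_fraction=0.10)
        )
        assert min(c.counts) >= math.ceil(0.10 * 80)

    def test_linear_bound_equality_at_k2(self, rng):
        for _ in range(10):
            x = np.round(rng.normal(size=15), 2)
            if np.unique(x).size < 2:
                continue
            got = adaptive_categorize(x, SearchConfig(k_fixed=2))
            ref = exhaustive_categorize(x, 2)
            assert got.loss == pytest.approx(ref.loss, rel=1e-12)


class TestQuantile:
    def test_even_split(self):
        c = quantile_categorize(np.arange(1, 9), 4)
        assert list(c.labels) == [0, 0, 1, 1, 2, 2, 3, 3]
        assert c.k == 4

    def test_median_split(self):
        c = quantile_categorize(np.arange(1, 9), 2)
        assert list(c.labels) == [0, 0, 0, 0, 1, 1, 1, 1]

    def test_tied_minimum_shares_label(self, rng):
        x = np.concatenate([np.full(60, 0.5), rng.uniform(1, 10, 40)])
        c = quantile_categorize(x, 4)
        assert np.all(c.labels[:60] == 0)
        assert c.k < 4  # collapsed cutoffs
        assert all(cnt > 0 for cnt in c.counts)

    def test_infeasible(self):
        with pytest.raises(InfeasibleKError):
            quantile_categorize([1.0, 1.0, 2.0, 2.0], 4)


finite_floats = st.floats(
    min_value=-1e4, max_value=1e4, allow_nan=False, allow_infinity=False
)


@st.composite
def duplicated_arrays(draw):
    base = draw(st.lists(finite_floats, min_size=4, max_size=20))
    reps = draw(st.lists(st.integers(1, 3), min_size=len(base), max_size=len(base)))
    vals = [round(v, 2) for v, r in zip(base, reps) for _ in range(r)]
    return np.array(vals, dtype=float)


@settings(max_examples=120, deadline=None)
@given(duplicated_arrays())
def test_adaptive_properties(values):
    """Label monotonicity, tie sharing, conservation, and F identity hold
    for every returned categorization."""
    c = adaptive_categorize(values)
    order = np.argsort(values, kind="stable")
    lab_sorted = c.labels[order]
    assert np.all(np.diff(lab_sorted) >= 0)  # monotone in the raw values
    for v in np.unique(values):
        assert np.unique(c.labels[values == v]).size == 1  # ties share a label
    if c.k >= 2 and values.size > c.k:
        lo, f, within, between = loss(values, c.labels, c.k)
        total = float(np.sum((values - values.mean()) ** 2))
        assert within + between == pytest.approx(total, rel=1e-9, abs=1e-9)
        assert lo == pytest.approx(c.loss, rel=1e-9, abs=1e-12)
        if within > 1e-10 * total:
            groups = [values[c.labels == i] for i in range(c.k)]
            ref = stats.f_oneway(*groups).statistic
            # 1e-6 here: hypothesis explores adversarial magnitude spreads
            # where f_oneway's shortcut formula itself loses precision; the
            # 1e-9 identity on ordinary inputs is asserted in acceptance
            assert f == pytest.approx(ref, rel=1e-6)
            assert lo * f == pytest.approx(1.0, rel=1e-12)


@settings(max_examples=60, deadline=None)
@given(duplicated_arrays(), st.integers(2, 3))
def test_linear_search_never_beats_exhaustive(values, k):
    if not (8 <= values.size <= 30) or np.unique(values).size <= k:
        return
    approx = adaptive_categorize(values, SearchConfig(k_fixed=k))
    exact = exhaustive_categorize(values, k)
    assert approx.loss >= exact.loss - 1e-12
    if k == 2:
        assert approx.loss == pytest.approx(exact.loss, rel=1e-12, abs=1e-15)


def test_log_pvalue_matches_scipy_in_normal_range():
    for f, d1, d2 in [(1.3, 2, 17), (4.0, 3, 40), (0.2, 1, 9), (30.0, 2, 100)]:
        assert f_test_log_pvalue(f, d1, d2) == pytest.approx(
            np.log(stats.f.sf(f, d1, d2)), rel=1e-9
        )


def test_log_pvalue_monotone_in_f_far_tail():
    lps = [f_test_log_pvalue(f, 3, 1496) for f in (10, 100, 1e3, 1e4, 1e5)]
    assert all(a > b for a, b in zip(lps, lps[1:]))
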