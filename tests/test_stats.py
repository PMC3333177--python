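"""Statistical primitives, each checked against an independent brute-force oracle."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from exomotif.stats import (
    bh_fdr,
    fisher_exact,
    kendall_tau,
    mwu_bootstrap,
    mwu_pvalue,
    skewness,
)

# ---------------------------------------------------------------------------
# oracles


def tau_b_oracle(x, y):
    """O(n^2) pair-counting Kendall tau-b."""
    n = len(x)
    c = d = tx = ty = 0
    for i, j in combinations(range(n), 2):
        sx = np.sign(x[j] - x[i])
        sy = np.sign(y[j] - y[i])
        if sx == 0:
            tx += 1
        if sy == 0:
            ty += 1
        if sx * sy > 0:
            c += 1
        elif sx * sy < 0:
            d += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return 0.0 if denom == 0 else (c - d) / denom


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, col1, total = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    probs = {x: hypergeom.pmf(x, total, row1, col1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def bh_oracle(ps):
    """Direct Benjamini-Hochberg step-up formula with monotone envelope."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, ps[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


# ---------------------------------------------------------------------------
# skewness


@pytest.mark.parametrize(
    "values, expected",
    [
        ([1, 2, 3], 0.0),
        ([5, 5, 5], 0.0),
        ([0, 0, 1], 1 / math.sqrt(2)),
    ],
)
def test_skewness_reference_values(values, expected):
    assert skewness(values) == pytest.approx(expected, abs=1e-12)


def test_skewness_empty_rejected():
    with pytest.raises(ValueError):
        skewness([])


@given(
    st.lists(st.integers(-50, 50), min_size=3, max_size=30),
    st.integers(-50, 50),
    st.sampled_from([0.5, 1.0, 2.0, 4.0]),
)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_skewness_shift_scale_negation(values, shift, scale):
    arr = np.asarray(values, dtype=float)
    g = skewness(arr)
    assert skewness(arr * scale + shift) == pytest.approx(g, abs=1e-8)
    assert skewness(-arr) == pytest.approx(-g, abs=1e-8)


# ---------------------------------------------------------------------------
# Kendall tau-b


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [10, 20, 30], 1.0),
        ([1, 2, 3], [30, 20, 10], -1.0),
        ([1, 1, 2], [1, 2, 3], 2 / math.sqrt(6)),
        ([1, 1, 1], [1, 2, 3], 0.0),  # constant-variable convention
    ],
)
def test_kendall_reference_values(x, y, expected):
    assert kendall_tau(x, y) == pytest.approx(expected, abs=1e-12)


def test_kendall_matches_pair_counting_oracle():
    rng = np.random.default_rng(42)
    for _ in range(40):
        n = int(rng.integers(2, 51))
        x = rng.integers(0, 8, n).astype(float)  # ties likely
        y = rng.integers(0, 8, n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        assert kendall_tau(x, y) == pytest.approx(tau_b_oracle(x, y), abs=1e-10)


def test_kendall_length_mismatch():
    with pytest.raises(ValueError):
        kendall_tau([1, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# Fisher's exact test


@pytest.mark.parametrize(
    "table, expected",
    [
        ([[5, 5], [5, 5]], 1.0),
        ([[10, 0], [0, 10]], 2 / math.comb(20, 10)),
        ([[0, 0], [3, 7]], 1.0),  # zero margin carries no information
    ],
)
def test_fisher_reference_values(table, expected):
    assert fisher_exact(table) == pytest.approx(expected, rel=1e-9)


def test_fisher_all_zero_rejected():
    with pytest.raises(ValueError):
        fisher_exact([[0, 0], [0, 0]])


def test_fisher_matches_enumeration_small_tables():
    for total in range(1, 13):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    d = total - a - b - c
                    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                        continue
                    assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                        fisher_oracle(a, b, c, d), rel=1e-8
                    ), (a, b, c, d)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR


@pytest.mark.parametrize(
    "ps, expected",
    [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
    ],
)
def test_bh_reference_values(ps, expected):
    assert bh_fdr(ps) == pytest.approx(expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_bh_matches_direct_formula_and_dominates_p(ps):
    q = bh_fdr(ps)
    assert q == pytest.approx(bh_oracle(ps), abs=1e-12)
    assert all(qi >= pi - 1e-12 for qi, pi in zip(q, ps))


def test_bh_permutation_equivariant():
    rng = np.random.default_rng(0)
    ps = rng.uniform(0, 1, 25)
    perm = rng.permutation(25)
    q = np.asarray(bh_fdr(ps))
    q_perm = np.asarray(bh_fdr(ps[perm]))
    assert q_perm == pytest.approx(q[perm])


# ---------------------------------------------------------------------------
# Mann-Whitney U


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [4, 5, 6], 2 / math.comb(6, 3)),
        ([1], [2], 1.0),
    ],
)
def test_mwu_exact_reference_values(x, y, expected):
    assert mwu_pvalue(x, y) == pytest.approx(expected, rel=1e-12)


def test_mwu_identical_multisets_near_one():
    assert mwu_pvalue([1, 2, 3, 4], [1, 2, 3, 4]) >= 0.99


def test_mwu_rejects_empty():
    with pytest.raises(ValueError):
        mwu_pvalue([], [1.0])


def test_mwu_large_sample_detects_shift():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 200)
    y = rng.normal(1.0, 1, 200)
    assert mwu_pvalue(x, y) < 1e-10
    assert mwu_pvalue(x, x) > 0.9


# ---------------------------------------------------------------------------
# bootstrap-stabilized Mann-Whitney


def test_bootstrap_full_resample_equals_plain_mwu():
    # both samples no larger than the rule size: every round is the full test
    x = [1.0, 2.0, 3.0, 7.0]
    y = [4.0, 5.0, 6.0, 8.0]
    res = mwu_bootstrap(x, y, sample_size_rule="min_sample", seed=1)
    assert res.converged and res.p_sd <= 1e-12 and res.n_rounds == 3
    assert res.p_mean == pytest.approx(mwu_pvalue(x, y))


def test_bootstrap_converges_on_well_separated_samples():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1, 500)
    y = rng.normal(30, 1, 500)  # large offset: complete separation
    res = mwu_bootstrap(x, y, sample_size_rule="fixed_100", seed=3)
    assert res.converged
    assert res.p_mean < 1e-3


def test_bootstrap_deterministic_per_seed():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 80)
    y = rng.normal(0.5, 1, 90)
    r1 = mwu_bootstrap(x, y, seed=17)
    r2 = mwu_bootstrap(x, y, seed=17)
    assert r1 == r2


def test_bootstrap_convergence_invariant():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 150)
    y = rng.normal(0.2, 1, 150)
    res = mwu_bootstrap(x, y, sample_size_rule="fixed_100", seed=8, max_rounds=50)
    if res.converged:
        assert res.p_sd <= 0.10 * res.p_mean or (
            res.p_mean <= 1e-15 and res.p_sd <= 1e-15
        )
    else:
        assert res.n_rounds == 50
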