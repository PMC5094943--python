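"""Statistical kernel: frozen small-sample values, brute-force oracles, properties."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats as sps

from sigshift.data import GeneSetCollection, ValidationError
from sigshift.stats import (
    bh_adjust,
    conditional_hypergeom_enrich,
    delta_delta_ct,
    fisher_exact,
    hypergeom_enrich,
    protected_lsd,
    rank_correlation,
    rank_sum_test,
    signed_rank_test,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_rank_sum_p(x, y, alternative):
    """Enumerate every assignment of the pooled values to the two samples."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * (len(pooled) - n1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    if alternative == "less":
        return np.mean(us <= obs_u + 1e-9)
    if alternative == "greater":
        return np.mean(us >= obs_u - 1e-9)
    return np.mean(np.abs(us - mu) >= abs(obs_u - mu) - 1e-9)


def brute_signed_rank_p(d, alternative):
    d = np.asarray([v for v in d if v != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    if alternative == "less":
        return np.mean(ws <= obs + 1e-9)
    if alternative == "greater":
        return np.mean(ws >= obs - 1e-9)
    return np.mean(np.abs(ws - mu) >= abs(obs - mu) - 1e-9)


def brute_fisher_two_sided(table):
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
           for k in range(lo, hi + 1)}
    return sum(v for v in pmf.values() if v <= pmf[a] * (1 + 1e-7))


# ---------------------------------------------------------------------------
# frozen examples


@pytest.mark.parametrize("x,y,alt,expected", [
    ([1], [2], "less", 0.5),
    ([1, 2, 3], [4, 5, 6], "less", 0.05),
    ([4, 5, 6], [1, 2, 3], "greater", 0.05),
])
def test_rank_sum_exact_examples(x, y, alt, expected):
    res = rank_sum_test(x, y, alternative=alt)
    assert res.method == "exact-enumeration"
    assert res.p_value == pytest.approx(expected, abs=1e-12)


def test_rank_sum_all_tied_is_no_evidence():
    res = rank_sum_test([3, 3, 3], [3, 3, 3])
    assert res.p_value == 1.0


def test_rank_sum_empty_input_rejected():
    with pytest.raises(ValidationError):
        rank_sum_test([], [1.0])


@pytest.mark.parametrize("d,alt,expected", [
    ([1, 2, 3], "greater", 1 / 8),
    ([-1, -2, -3], "less", 1 / 8),
])
def test_signed_rank_exact_examples(d, alt, expected):
    res = signed_rank_test(d, alternative=alt)
    assert res.method == "exact-enumeration"
    assert res.p_value == pytest.approx(expected, abs=1e-12)


def test_signed_rank_all_zero_flagged():
    res = signed_rank_test([0, 0])
    assert res.p_value == 1.0
    assert "degenerate" in res.method


def test_signed_rank_approximation_near_exact_at_switch_point():
    # tie-free n=15 data: exact path vs the tie-corrected normal approximation
    rng = np.random.default_rng(4)
    d = rng.normal(0.3, 1.0, size=15)
    exact = signed_rank_test(d, alternative="greater")
    assert exact.method == "exact-enumeration"
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    approx = sps.norm.sf((w - mu - 0.5) / sd)
    assert abs(exact.p_value - approx) < 1e-2


def test_fisher_exact_examples():
    assert fisher_exact([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)
    assert fisher_exact([[5, 0], [5, 0]]).p_value == 1.0
    obs = fisher_exact([[8, 2], [2, 8]])
    assert obs.p_value == pytest.approx(brute_fisher_two_sided([[8, 2], [2, 8]]), abs=1e-12)


def test_fisher_zero_total_rejected():
    with pytest.raises(ValidationError):
        fisher_exact([[0, 0], [0, 0]])


def test_hypergeom_examples():
    assert hypergeom_enrich(2, 2, 2, 10).p_value == pytest.approx(1 / 45)
    assert hypergeom_enrich(0, 5, 5, 20).p_value == 1.0
    assert hypergeom_enrich(4, 4, 4, 4).p_value == 1.0
    with pytest.raises(ValidationError):
        hypergeom_enrich(5, 4, 5, 10)


# ---------------------------------------------------------------------------
# oracle sweeps: exact paths agree with brute-force enumeration


def test_rank_sum_matches_enumeration_oracle():
    rng = np.random.default_rng(1)
    for _ in range(30):
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 10 - n1 + 1))
        x = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
        y = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), x)
        for alt in ("two-sided", "greater", "less"):
            mine = rank_sum_test(x, y, alternative=alt)
            assert mine.method == "exact-enumeration"
            assert mine.p_value == pytest.approx(brute_rank_sum_p(x, y, alt), abs=1e-12)


def test_rank_sum_exact_matches_scipy():
    rng = np.random.default_rng(2)
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(2, 6)))
        y = rng.normal(size=int(rng.integers(2, 6)))
        mine = rank_sum_test(x, y, alternative="two-sided")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert mine.statistic == pytest.approx(ref.statistic)


def test_signed_rank_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = int(rng.integers(1, 13))
        d = rng.normal(size=n)
        for alt in ("two-sided", "greater", "less"):
            mine = signed_rank_test(d, alternative=alt)
            assert mine.method == "exact-enumeration"
            assert mine.p_value == pytest.approx(brute_signed_rank_p(d, alt), abs=1e-12)


def test_fisher_matches_scipy_and_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(40):
        t = rng.integers(0, 9, size=(2, 2))
        if t.sum() == 0 or t.sum() > 30:
            continue
        mine = fisher_exact(t, alternative="two-sided")
        _, ref = sps.fisher_exact(t, alternative="two-sided")
        assert mine.p_value == pytest.approx(ref, abs=1e-10)
        if all(m > 0 for m in [*t.sum(0), *t.sum(1)]):
            assert mine.p_value == pytest.approx(brute_fisher_two_sided(t.tolist()), abs=1e-12)


def test_hypergeom_matches_combinatorial_oracle():
    rng = np.random.default_rng(6)
    for _ in range(30):
        universe = int(rng.integers(2, 25))
        uh = int(rng.integers(0, universe + 1))
        size = int(rng.integers(1, universe + 1))
        lo = max(0, size - (universe - uh))
        hits = int(rng.integers(lo, min(size, uh) + 1))
        p_oracle = sum(
            math.comb(uh, k) * math.comb(universe - uh, size - k)
            for k in range(hits, min(size, uh) + 1)
        ) / math.comb(universe, size)
        assert hypergeom_enrich(hits, size, uh, universe).p_value == pytest.approx(
            p_oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_examples_and_statsmodels_agreement():
    assert bh_adjust([0.05]) == pytest.approx([0.05])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    p = rng.random(200)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    assert bh_adjust(p) == pytest.approx(ref, abs=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st_.lists(st_.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_dominates_and_is_permutation_equivariant(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all(adj <= 1.0)
    # sorted order of adjusted values follows sorted order of raw p
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-15)
    # permuting then adjusting equals adjusting then permuting
    perm = np.roll(np.arange(len(p)), 1)
    assert bh_adjust(np.asarray(p)[perm]) == pytest.approx(adj[perm])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# rank correlation


def test_rank_correlation_examples():
    assert rank_correlation([1, 2, 3, 4], [2, 4, 8, 16]) == pytest.approx(1.0)
    assert rank_correlation([1, 2, 3, 4], [5, 4, 3, 1]) == pytest.approx(-1.0)
    assert rank_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
    assert math.isnan(rank_correlation([1, 2, 3], [5, 5, 5]))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st_.lists(st_.integers(min_value=-1000, max_value=1000), min_size=3,
                 max_size=20, unique=True).map(sorted))
def test_rank_correlation_invariant_under_monotone_transform(x):
    x = [v / 20.0 for v in x]
    rng = np.random.default_rng(8)
    y = rng.normal(size=len(x))
    if np.ptp(sps.rankdata(y)) == 0:
        return
    base = rank_correlation(x, y)
    assert rank_correlation(np.exp(np.asarray(x) / 25.0), y) == pytest.approx(base, abs=1e-12)
    assert rank_correlation(x, 3.0 * np.asarray(y) ** 3) == pytest.approx(
        rank_correlation(x, np.asarray(y) ** 3), abs=1e-12)


def test_rank_correlation_matches_scipy():
    rng = np.random.default_rng(9)
    x, y = rng.normal(size=50), rng.normal(size=50)
    assert rank_correlation(x, y) == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)


# ---------------------------------------------------------------------------
# protected LSD letter display


def test_lsd_identical_groups_share_one_letter(rng):
    noise = rng.normal(0, 1, size=5)
    groups = {f"g{i}": noise + 0.01 * rng.normal(size=5) for i in range(4)}
    ld = protected_lsd(groups)
    assert set(ld.letters.values()) == {"a"}


def test_lsd_two_groups_match_pooled_t(rng):
    a = rng.normal(0, 1, size=6)
    b = rng.normal(4, 1, size=6)
    ld = protected_lsd({"a": a, "b": b})
    ref = sps.ttest_ind(a, b)  # pooled-variance two-sample t
    assert ld.pairwise_p.loc["a", "b"] == pytest.approx(ref.pvalue, abs=1e-12)
    assert ld.letters["a"] != ld.letters["b"]


def test_lsd_letters_match_pairwise_matrix(rng):
    for trial in range(10):
        k = int(rng.integers(3, 6))
        groups = {f"g{i}": rng.normal(rng.normal(0, 1.2), 1.0, size=5) for i in range(k)}
        ld = protected_lsd(groups, protect=False)
        for gi in groups:
            assert ld.letters[gi]
            for gj in groups:
                if gi == gj:
                    continue
                share = bool(set(ld.letters[gi]) & set(ld.letters[gj]))
                assert share == (ld.pairwise_p.loc[gi, gj] >= ld.alpha)


def test_lsd_partition_invariant_to_group_order(rng):
    groups = {g: rng.normal(m, 1, size=5) for g, m in [("a", 0), ("b", 3), ("c", 3.2)]}
    ld1 = protected_lsd(groups)
    ld2 = protected_lsd(dict(reversed(list(groups.items()))))
    same1 = {(i, j): bool(set(ld1.letters[i]) & set(ld1.letters[j])) for i in groups for j in groups}
    same2 = {(i, j): bool(set(ld2.letters[i]) & set(ld2.letters[j])) for i in groups for j in groups}
    assert same1 == same2


def test_lsd_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        protected_lsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
    with pytest.raises(ValidationError):
        protected_lsd({"a": [1.0, 2.0]})


def test_protection_gate_collapses_letters(rng):
    groups = {f"g{i}": rng.normal(0, 1, size=3) for i in range(4)}
    ld = protected_lsd(groups, protect=True)
    if ld.f_p >= ld.alpha:
        assert set(ld.letters.values()) == {"a"}


# ---------------------------------------------------------------------------
# ddCt and conditional hypergeometric


@pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
def test_delta_delta_ct(ddct, expected):
    assert delta_delta_ct(20.0 + ddct, 20.0, 0.0) == pytest.approx(expected)


def test_conditional_hypergeom_subtracts_significant_child_hits():
    universe = [f"g{i}" for i in range(40)]
    child = universe[:8]
    parent = universe[:16]
    hits = universe[:8] + universe[30:32]
    sets = GeneSetCollection({"parent": parent, "child": child})
    plain = conditional_hypergeom_enrich(hits, sets, universe)
    cond = conditional_hypergeom_enrich(hits, sets, universe,
                                        children={"parent": ["child"]})
    p_child = cond.set_index("set").loc["child", "p"]
    assert p_child == plain.set_index("set").loc["child", "p"]
    # the child is significant, so its hits no longer count for the parent
    assert cond.set_index("set").loc["parent", "p"] > plain.set_index("set").loc["parent", "p"]
    assert cond.set_index("set").loc["parent", "hits"] == 0
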