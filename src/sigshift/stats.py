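"""Statistical primitives shared by every pipeline stage.

Rank-based tests use mid-ranks for ties. Exact null enumeration is used at
small sample sizes (rank-sum: combined n <= 12 without ties; signed-rank:
n <= 15; Fisher: always) and a tie-corrected, continuity-corrected normal
approximation otherwise; the ``method`` tag of every result names the path
taken so the computation is auditable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from sigshift.data import ValidationError

logger = logging.getLogger("sigshift")

ALTERNATIVES = ("two-sided", "greater", "less")

RANK_SUM_EXACT_MAX_N = 12
SIGNED_RANK_EXACT_MAX_N = 15

_EPS = 1e-9


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0 + 1e-15):
            raise ValidationError(f"p-value out of (0,1]: {self.p_value}")
        self.p_value = min(self.p_value, 1.0)


def _check_alternative(alternative: str) -> None:
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {ALTERNATIVES}, got {alternative!r}")


def rank_sum_test(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon-Mann-Whitney rank sum test of two independent samples.

    The statistic is the Mann-Whitney U of ``x`` relative to ``y`` (number of
    (x, y) pairs with x > y, ties counted half). ``alternative='less'`` means
    x tends to be smaller than y.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires non-empty samples")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if n <= RANK_SUM_EXACT_MAX_N and not has_ties:
        # exact null: U over all C(n, n1) equally likely rank assignments
        all_ranks = np.arange(1, n + 1)
        us = np.array([
            sum(c) - n1 * (n1 + 1) / 2.0
            for c in itertools.combinations(all_ranks, n1)
        ])
        total = us.size
        if alternative == "less":
            p = np.sum(us <= u + _EPS) / total
        elif alternative == "greater":
            p = np.sum(us >= u - _EPS) / total
        else:
            p = np.sum(np.abs(us - mu) >= abs(u - mu) - _EPS) / total
        return TestResult(u, max(p, 1.0 / total), alternative, "exact-enumeration")

    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(u, 1.0, alternative, "degenerate-all-tied")
    sd = math.sqrt(var)
    if alternative == "less":
        z = (u - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    elif alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = sps.norm.sf(z)
    else:
        z = (abs(u - mu) - 0.5) / sd
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return TestResult(u, min(max(p, np.nextafter(0, 1)), 1.0), alternative,
                      "normal-approximation")


def signed_rank_test(d, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed rank test on paired differences (zeros dropped).

    Statistic is W+, the sum of ranks of positive differences.
    """
    _check_alternative(alternative)
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValidationError("signed_rank_test requires non-empty input")
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, 1.0, alternative, "degenerate-all-zero")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # n(n+1)/2
    mu = total / 2.0

    if n <= SIGNED_RANK_EXACT_MAX_N:
        # exact null: W+ over all 2^n equally likely sign patterns
        masks = np.arange(2**n, dtype=np.uint32)
        bits = (masks[:, None] >> np.arange(n)) & 1
        ws = bits @ ranks
        m = ws.size
        if alternative == "less":
            p = np.sum(ws <= w_pos + _EPS) / m
        elif alternative == "greater":
            p = np.sum(ws >= w_pos - _EPS) / m
        else:
            p = np.sum(np.abs(ws - mu) >= abs(w_pos - mu) - _EPS) / m
        return TestResult(w_pos, max(p, 1.0 / m), alternative, "exact-enumeration")

    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return TestResult(w_pos, 1.0, alternative, "degenerate-all-tied")
    sd = math.sqrt(var)
    if alternative == "less":
        p = sps.norm.cdf((w_pos - mu + 0.5) / sd)
    elif alternative == "greater":
        p = sps.norm.sf((w_pos - mu - 0.5) / sd)
    else:
        z = (abs(w_pos - mu) - 0.5) / sd
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return TestResult(w_pos, min(max(p, np.nextafter(0, 1)), 1.0), alternative,
                      "normal-approximation")


def fisher_exact(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table of non-negative counts.

    The two-sided p-value sums the probabilities of all tables (with the
    observed margins) whose probability does not exceed the observed table's.
    """
    _check_alternative(alternative)
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"fisher_exact requires a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValidationError("fisher_exact requires non-negative integer counts")
    a, b = int(round(t[0, 0])), int(round(t[0, 1]))
    c, d = int(round(t[1, 0])), int(round(t[1, 1]))
    grand = a + b + c + d
    if grand == 0:
        raise ValidationError("fisher_exact: zero grand total")
    r1, c1 = a + b, a + c
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    if r1 == 0 or c1 == 0 or r1 == grand or c1 == grand:
        return TestResult(odds, 1.0, alternative, "degenerate-margin")

    lo, hi = max(0, r1 + c1 - grand), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, grand, r1, c1)
    p_obs = float(sps.hypergeom.pmf(a, grand, r1, c1))
    if alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return TestResult(odds, min(max(p, np.nextafter(0, 1)), 1.0), alternative,
                      "hypergeometric-enumeration")


def hypergeom_enrich(hits: int, set_size: int, universe_hits: int,
                     universe_size: int) -> TestResult:
    """Upper-tail hypergeometric over-representation test.

    Probability of drawing at least ``hits`` marked genes in a sample of
    ``set_size`` from a universe of ``universe_size`` containing
    ``universe_hits`` marked genes.
    """
    vals = (hits, set_size, universe_hits, universe_size)
    if any(v < 0 for v in vals):
        raise ValidationError(f"negative count in {vals}")
    if hits > set_size or set_size > universe_size or hits > universe_hits \
            or universe_hits > universe_size \
            or set_size - hits > universe_size - universe_hits:
        raise ValidationError(f"inconsistent hypergeometric counts {vals}")
    p = float(sps.hypergeom.sf(hits - 1, universe_size, universe_hits, set_size))
    return TestResult(float(hits), min(max(p, np.nextafter(0, 1)), 1.0),
                      "greater", "hypergeometric-upper-tail")


def conditional_hypergeom_enrich(hit_genes, gene_sets, universe,
                                 children=None, alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of each gene set among ``hit_genes``.

    When a parent-to-children map is supplied, sets are tested children first
    and, in a single pass, hits already explained by a significant child
    (p < ``alpha``) are removed from the parent before it is tested.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    hits_all = set(hit_genes) & uni
    children = {k: list(v) for k, v in (children or {}).items()}

    order: list[str] = []
    seen: set[str] = set()

    def visit(name):
        if name in seen:
            return
        seen.add(name)
        for ch in children.get(name, []):
            if ch in gene_sets.sets:
                visit(ch)
        order.append(name)

    for name in gene_sets.sets:
        visit(name)

    claimed: dict[str, set[str]] = {}
    rows = []
    for name in order:
        members = set(gene_sets[name]) & uni
        excluded: set[str] = set()
        for ch in children.get(name, []):
            excluded |= claimed.get(ch, set())
        eff_members = members - excluded
        eff_universe = len(uni - excluded)
        eff_hits_all = len(hits_all - excluded)
        n_hit = len(eff_members & hits_all)
        if len(eff_members) == 0:
            rows.append((name, 0, 0, 1.0))
            continue
        res = hypergeom_enrich(n_hit, len(eff_members), eff_hits_all, eff_universe)
        rows.append((name, n_hit, len(eff_members), res.p_value))
        if res.p_value < alpha:
            claimed[name] = (members & hits_all) | excluded
    df = pd.DataFrame(rows, columns=["set", "hits", "set_size", "p"])
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set"]).reset_index(drop=True)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def rank_correlation(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("rank_correlation requires equal-length vectors")
    if x.size < 3:
        raise ValidationError("rank_correlation requires n >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("rank_correlation: constant vector, correlation undefined")
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass
class LetterDisplay:
    """Compact letter display from protected-LSD pairwise comparisons.

    Two groups share a letter iff their pairwise p >= alpha (all groups share
    one letter when the omnibus F test is not significant and protection is on).
    """

    letters: dict[str, str]
    pairwise_p: pd.DataFrame
    mse: float
    error_df: int
    f_p: float
    alpha: float


def _assign_letters(groups: list[str], sig_pairs: set[frozenset]) -> dict[str, str]:
    # insert-and-absorb: split every letter set containing a significant pair,
    # then drop letter sets contained in another
    letter_sets: list[set] = [set(groups)]
    for pair in sig_pairs:
        i, j = tuple(pair)
        new_sets: list[set] = []
        for s in letter_sets:
            if i in s and j in s:
                new_sets.extend([s - {i}, s - {j}])
            else:
                new_sets.append(s)
        letter_sets = [s for s in new_sets if s]
        # absorb: remove sets that are subsets of another
        keep = []
        for s in letter_sets:
            if not any(s < t for t in letter_sets) and s not in keep:
                keep.append(s)
        letter_sets = keep
    # order letters by the first group (in input order) they contain
    pos = {g: k for k, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(pos[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for idx, s in enumerate(letter_sets):
        ch = alphabet[idx % len(alphabet)] * (1 + idx // len(alphabet))
        for g in s:
            out[g] += ch
    return {g: "".join(sorted(out[g])) for g in groups}


def protected_lsd(values_by_group: dict, alpha: float = 0.05,
                  protect: bool = True) -> LetterDisplay:
    """Fisher's least-significant-difference comparisons with letter display.

    One-way ANOVA supplies the pooled error variance; pairwise t tests use the
    pooled MSE and its degrees of freedom. With ``protect`` (the default), a
    non-significant omnibus F collapses all groups onto one letter.
    """
    groups = {str(g): np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValidationError("protected_lsd requires >= 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has n < 2")
    names = sorted(groups, key=lambda g: -float(np.mean(groups[g])))
    k = len(names)
    ns = {g: groups[g].size for g in names}
    means = {g: float(np.mean(groups[g])) for g in names}
    n_total = sum(ns.values())
    sse = sum(float(np.sum((groups[g] - means[g]) ** 2)) for g in names)
    df_e = n_total - k
    mse = sse / df_e
    if mse <= 0:
        raise ValidationError("zero within-group variance in every group; LSD undefined")
    grand = sum(means[g] * ns[g] for g in names) / n_total
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in names)
    f_stat = (ssb / (k - 1)) / mse
    f_p = float(sps.f.sf(f_stat, k - 1, df_e))

    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    sig_pairs: set[frozenset] = set()
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            se = math.sqrt(mse * (1.0 / ns[gi] + 1.0 / ns[gj]))
            tstat = (means[gi] - means[gj]) / se
            p = float(2.0 * sps.t.sf(abs(tstat), df_e))
            pmat.loc[gi, gj] = pmat.loc[gj, gi] = p
            if p < alpha:
                sig_pairs.add(frozenset((gi, gj)))

    if protect and f_p >= alpha:
        letters = {g: "a" for g in names}
    else:
        letters = _assign_letters(names, sig_pairs)
    return LetterDisplay(letters, pmat, mse, df_e, f_p, alpha)


def delta_delta_ct(ct_target, ct_endogenous, calibrator_delta: float):
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(endogenous control); ddCt = dCt - calibrator dCt;
    relative expression = 2^-ddCt, so the calibrator level is 1 by definition.
    Accepts scalars or arrays.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_endogenous = np.asarray(ct_endogenous, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_endogenous))
            and np.isfinite(calibrator_delta)):
        raise ValidationError("Ct values must be finite")
    ddct = (ct_target - ct_endogenous) - calibrator_delta
    out = 2.0 ** (-ddct)
    return float(out) if out.ndim == 0 else out
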