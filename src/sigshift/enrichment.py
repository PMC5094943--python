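"""Directional signature-enrichment statistics against a fold-change vector.

Given per-gene fold changes from one comparison and a signature gene set,
three complementary statistics quantify a directional shift of the signature
relative to the non-signature background:

* rank-sum bias: Wilcoxon rank sum test of signature vs background log2FCs,
  summarized as a signed Log10P (positive when the signature median exceeds
  the background median);
* direction counts: Fisher's exact test on the 2x2 table of up (FC > 1)
  versus down (FC <= 1) genes in signature and background, with the middle
  95% of the hypergeometric null for the up-count;
* cumulative-overlap AUC: genes ranked by the comparison statistic, area
  under the signature-overlap curve; equal to the Wilcoxon-Mann-Whitney
  U / (n1 * n2), so 0.5 is the no-enrichment diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from sigshift.data import EnrichmentResult, FCVector, SignatureSet, ValidationError
from sigshift.stats import TestResult, fisher_exact, rank_sum_test

logger = logging.getLogger("sigshift")

P_FLOOR = 1e-300


def _signature_genes(sig) -> tuple[str, list[str]]:
    if isinstance(sig, SignatureSet):
        return sig.name, list(sig.genes)
    if isinstance(sig, (list, tuple, set, frozenset)):
        return "signature", [str(g) for g in sig]
    raise ValidationError(f"unsupported signature type {type(sig).__name__}")


def _split(fc: FCVector, sig) -> tuple[str, np.ndarray, np.ndarray, pd.Index, int]:
    name, genes = _signature_genes(sig)
    present = fc.log2fc.index.intersection(pd.Index(genes))
    dropped = len(genes) - len(present)
    if dropped:
        logger.info("signature %r: %d genes absent from the FC vector, dropped",
                    name, dropped)
    if len(present) == 0:
        raise ValidationError(f"no gene of signature {name!r} present in the FC vector")
    mask = fc.log2fc.index.isin(present)
    sig_l2 = fc.log2fc.to_numpy()[mask]
    bg_l2 = fc.log2fc.to_numpy()[~mask]
    if bg_l2.size == 0:
        raise ValidationError(
            f"signature {name!r} covers the entire FC vector; no background left"
        )
    return name, sig_l2, bg_l2, present, dropped


def signed_log10p(p: float, direction_sign: float) -> float:
    """-log10(p) carrying the sign of the signature-vs-background shift."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p out of [0,1]: {p}")
    if p == 0.0:
        logger.warning("signed_log10p: p = 0 clamped to %.3g", P_FLOOR)
        p = P_FLOOR
    return float(-np.log10(p) * np.sign(direction_sign))


def direction_count_test(fc: FCVector, sig, band: float = 0.95):
    """Fisher's exact test of up/down direction counts, with the null band.

    Directions are dichotomized at linear FC = 1 (log2FC 0); ties at exactly
    1 count as down. Returns the test result; ``extra`` carries the counts
    and the central ``band`` interval of the hypergeometric null for the
    number of up-signature genes.
    """
    name, sig_l2, bg_l2, _, dropped = _split(fc, sig)
    n_up = int(np.sum(sig_l2 > 0))
    n_down = int(sig_l2.size - n_up)
    bg_up = int(np.sum(bg_l2 > 0))
    bg_down = int(bg_l2.size - bg_up)
    res = fisher_exact([[n_up, n_down], [bg_up, bg_down]], alternative="two-sided")
    n_total = sig_l2.size + bg_l2.size
    total_up = n_up + bg_up
    rv = sps.hypergeom(n_total, total_up, sig_l2.size)
    tail = (1.0 - band) / 2.0
    band_lo, band_hi = int(rv.ppf(tail)), int(rv.ppf(1.0 - tail))
    return TestResult(res.statistic, res.p_value, res.alternative, res.method, extra={
        "signature": name,
        "n_up": n_up, "n_down": n_down, "bg_up": bg_up, "bg_down": bg_down,
        "null_band": (band_lo, band_hi), "n_dropped": dropped,
    })


@dataclass
class OverlapCurve:
    """Cumulative overlap of a signature along a ranked gene list."""

    rank_fraction: np.ndarray   # x of the display curve: rank / n_total, in [0,1]
    overlap_fraction: np.ndarray  # y: cumulative signature count / n_sig
    cum_counts: np.ndarray      # raw cumulative signature counts per rank
    auc: float
    p_value: float

    @property
    def auc_minus_half(self) -> float:
        return self.auc - 0.5


def overlap_curve(fc: FCVector, sig, ascending: bool = False) -> OverlapCurve:
    """Signature overlap along genes ranked by the comparison statistic.

    Genes are ranked by log2FC (descending by default, so "most increased"
    first). The display curve is cumulative signature count against rank,
    normalized to the unit square. The AUC is the trapezoidal area of the
    overlap-vs-background step curve, grouping tied statistics into diagonal
    segments; this equals the Wilcoxon-Mann-Whitney U/(n1*n2) with mid-rank
    ties, so AUC > 0.5 means the signature is shifted toward the top of the
    ranking. Significance is the two-sided rank-sum p on the same split.
    """
    name, sig_l2, bg_l2, present, _ = _split(fc, sig)
    stat = fc.log2fc.to_numpy()
    is_sig = fc.log2fc.index.isin(present)
    order = np.argsort(-stat if not ascending else stat, kind="mergesort")
    sig_sorted = is_sig[order]
    cum = np.cumsum(sig_sorted)
    n_total = stat.size
    n1 = int(is_sig.sum())
    n2 = n_total - n1

    # AUC via mid-ranks of the ranking statistic (trapezoid over tie groups)
    ranks = sps.rankdata(stat if ascending else -stat)
    # low rank = top of the list; convert so larger score = nearer the top
    score = n_total + 1 - ranks
    u = float(score[is_sig].sum() - n1 * (n1 + 1) / 2.0)
    auc = u / (n1 * n2)
    p = rank_sum_test(sig_l2, bg_l2, alternative="two-sided").p_value

    x = np.arange(0, n_total + 1) / n_total
    y = np.concatenate([[0], cum]) / n1
    return OverlapCurve(x, y, np.concatenate([[0], cum]), auc, p)


def directional_bias(fc: FCVector, sig) -> EnrichmentResult:
    """Full directional-bias summary of one signature against one FC vector.

    The rank-sum p compares signature and non-signature log2FCs (two-sided);
    quartiles summarize the linear FC distributions; the signed Log10P takes
    the sign of (signature median log2FC - background median log2FC).
    Direction counts with their exact test and the overlap AUC are included.
    """
    name, sig_l2, bg_l2, _, dropped = _split(fc, sig)
    rs = rank_sum_test(sig_l2, bg_l2, alternative="two-sided")
    shift = float(np.median(sig_l2) - np.median(bg_l2))
    slp = signed_log10p(rs.p_value, shift)
    sig_fc = 2.0 ** sig_l2
    bg_fc = 2.0 ** bg_l2
    dc = direction_count_test(fc, sig)
    curve = overlap_curve(fc, sig)
    return EnrichmentResult(
        signature=name,
        n_used=int(sig_l2.size),
        n_dropped=dropped,
        mean_fc=float(np.mean(sig_fc)),
        sig_fc_quartiles=tuple(np.percentile(sig_fc, [25, 50, 75])),
        bg_fc_quartiles=tuple(np.percentile(bg_fc, [25, 50, 75])),
        rank_sum_p=rs.p_value,
        signed_log10p=slp,
        n_up=dc.extra["n_up"],
        n_down=dc.extra["n_down"],
        bg_up=dc.extra["bg_up"],
        bg_down=dc.extra["bg_down"],
        direction_p=dc.p_value,
        null_band=dc.extra["null_band"],
        auc=curve.auc,
    )


def rank_signatures(fc: FCVector, signatures) -> list[EnrichmentResult]:
    """Directional bias of every signature, sorted by signed Log10P descending.

    ``signatures`` is a mapping of name -> SignatureSet or gene list, or a
    GeneSetCollection. Signatures with no gene in the FC vector are skipped
    with a warning.
    """
    items = signatures if isinstance(signatures, dict) else dict(signatures)
    if len(items) == 0:
        raise ValidationError("rank_signatures requires at least one signature")
    results = []
    for name, sig in items.items():
        if isinstance(sig, SignatureSet):
            res = directional_bias(fc, sig)
        else:
            try:
                res = directional_bias(fc, list(sig))
            except ValidationError as err:
                logger.warning("skipping signature %r: %s", name, err)
                continue
            res.signature = name
        if isinstance(sig, SignatureSet):
            res.signature = sig.name
        results.append(res)
    results.sort(key=lambda r: (-r.signed_log10p, r.signature))
    return results


def compare_rankings(fc_a: FCVector, fc_b: FCVector, signatures) -> pd.DataFrame:
    """Per-signature difference of signed Log10P between two comparisons.

    Positive delta means the signature's bias toward increased expression is
    stronger in ``fc_a`` than in ``fc_b``.
    """
    res_a = {r.signature: r for r in rank_signatures(fc_a, signatures)}
    res_b = {r.signature: r for r in rank_signatures(fc_b, signatures)}
    common = sorted(set(res_a) & set(res_b))
    rows = []
    for name in common:
        rows.append({
            "signature": name,
            "signed_log10p_a": res_a[name].signed_log10p,
            "signed_log10p_b": res_b[name].signed_log10p,
            "delta_signed_log10p": res_a[name].signed_log10p - res_b[name].signed_log10p,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["delta_signed_log10p", "signature"],
                            ascending=[False, True]).reset_index(drop=True)
    return df
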