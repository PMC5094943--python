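"""Moderated differential expression for two-group and genotype-by-age designs.

Gene-wise least squares on log2 intensities with empirical-Bayes shrinkage of
the residual variances: each gene's variance estimate s_g^2 (d_g residual df)
is shrunk toward a prior s0^2 with d0 prior degrees of freedom,

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t = log2FC / (s_tilde_g * c) is referred to a t distribution
with d0 + d_g df (standard normal when d0 is infinite). The hyperparameters
(d0, s0^2) are estimated by closed-form moment matching on the log variances
via digamma/trigamma identities, the canonical formulation for microarray-scale
experiments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from sigshift.data import Config, DEResult, ExpressionMatrix, SampleTable, ValidationError
from sigshift.stats import bh_adjust, signed_rank_test

logger = logging.getLogger("sigshift")


@dataclass
class EBayesHyper:
    """Empirical-Bayes variance prior: d0 prior df, s0^2 prior variance."""

    prior_df: float
    prior_var: float
    residual_df: float

    def __post_init__(self):
        if not self.prior_df > 0:
            raise ValidationError(f"prior df must be positive, got {self.prior_df}")
        if not self.prior_var > 0:
            raise ValidationError(f"prior variance must be positive, got {self.prior_var}")


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_ebayes(s2: np.ndarray, df: float) -> EBayesHyper:
    """Moment estimator of (d0, s0^2) from gene-wise variances with common df.

    Matches mean and variance of log(s^2), whose null distribution is a scaled
    log-F; uses digamma/trigamma moments of log chi-square variables.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValidationError("need >= 2 positive gene variances to estimate the prior")
    z = np.log(s2)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = float("inf")
        s0_2 = math.exp(emean)
    return EBayesHyper(d0, s0_2, df)


def detection_call(pm, mm, alpha: float = 0.05) -> bool:
    """Above-background call for one probe set in one sample.

    One-sided signed-rank test that perfect-match intensities exceed their
    paired mismatch intensities; detected iff p < alpha.
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape:
        raise ValidationError(f"PM/MM length mismatch: {pm.shape} vs {mm.shape}")
    if pm.size < 4:
        raise ValidationError("detection_call requires >= 4 probe pairs")
    res = signed_rank_test(pm - mm, alternative="greater")
    return bool(res.p_value < alpha)


def gene_detection_call(probe_sets, alpha: float = 0.05) -> bool:
    """A gene is detected iff at least one of its probe sets is detected."""
    if len(probe_sets) == 0:
        raise ValidationError("gene has no probe sets")
    return any(detection_call(pm, mm, alpha=alpha) for pm, mm in probe_sets)


def expression_filter(detection: pd.DataFrame, samples_in_comparison,
                      min_fraction: float = 1.0 / 3.0) -> list[str]:
    """Genes detected in at least ``min_fraction`` of the comparison samples.

    A gene is included iff its detected count is >= min_fraction * n, i.e.
    >= ceil(min_fraction * n) when the product is fractional.
    """
    samples = list(samples_in_comparison)
    if len(samples) == 0:
        raise ValidationError("expression_filter: empty comparison")
    missing = set(samples) - set(detection.columns)
    if missing:
        raise ValidationError(f"detection matrix missing samples {sorted(missing)}")
    required = int(math.ceil(min_fraction * len(samples) - 1e-9))
    counts = detection[samples].astype(bool).sum(axis=1)
    included = list(detection.index[counts >= required])
    logger.info("expression_filter: %d genes in, %d excluded, %d out (>=%d/%d detected)",
                len(detection), len(detection) - len(included), len(included),
                required, len(samples))
    return included


def _included_genes(matrix: ExpressionMatrix, samples: list[str], config: Config) -> pd.Index:
    if matrix.detection is None:
        return matrix.values.index
    return pd.Index(expression_filter(matrix.detection, samples,
                                      min_fraction=config.min_detect_fraction))


def _moderated_table(gene_ids, included_mask, mean_a, mean_b, effect, s2, df,
                     c_factor, prior_df, prior_var):
    """Shared moderated-t machinery for two-group and interaction fits."""
    inc = np.asarray(included_mask, dtype=bool)
    s2_inc = s2[inc]
    if prior_df is None:
        hyper = estimate_ebayes(s2_inc, df)
        d0, s0_2 = hyper.prior_df, hyper.prior_var
    else:
        d0 = float(prior_df)
        if prior_var is not None:
            s0_2 = float(prior_var)
        elif d0 == 0:
            s0_2 = 1.0  # irrelevant: zero prior weight
        else:
            base = estimate_ebayes(s2_inc, df)
            s0_2 = base.prior_var
        hyper = EBayesHyper(max(d0, np.finfo(float).tiny), s0_2, df)

    n = len(gene_ids)
    t = np.full(n, np.nan)
    p = np.full(n, np.nan)
    fdr = np.full(n, np.nan)
    if math.isinf(d0):
        s2_mod = np.full(s2_inc.shape, s0_2)
        df_total = np.inf
    else:
        s2_mod = (d0 * s0_2 + df * s2_inc) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_inc = effect[inc] / np.sqrt(s2_mod * c_factor)
    t_inc = np.where(np.isfinite(t_inc), t_inc, 0.0)
    if math.isinf(df_total):
        p_inc = 2.0 * sps.norm.sf(np.abs(t_inc))
    else:
        p_inc = 2.0 * sps.t.sf(np.abs(t_inc), df_total)
    p_inc = np.clip(p_inc, np.nextafter(0, 1), 1.0)
    t[inc] = t_inc
    p[inc] = p_inc
    fdr[inc] = bh_adjust(p_inc)

    table = pd.DataFrame({
        "mean_a": mean_a,
        "mean_b": mean_b,
        "log2fc": effect,
        "fc": 2.0 ** effect,
        "t": t,
        "p": p,
        "fdr": fdr,
        "included": inc,
    }, index=pd.Index(gene_ids, name="gene"))
    table.loc[~inc, ["log2fc", "fc", "mean_a", "mean_b"]] = np.nan
    return table, hyper


def fit_moderated(matrix: ExpressionMatrix, design: SampleTable, contrast,
                  group_column: str = "group", config: Config | None = None,
                  prior_df: float | None = None,
                  prior_var: float | None = None) -> DEResult:
    """Moderated-t differential expression for one two-group contrast.

    ``contrast`` is a ``(group_a, group_b)`` pair; positive log2FC means higher
    expression in ``group_a``. Genes failing the detection filter (when the
    matrix carries detection calls) are retained as excluded rows. BH
    adjustment is applied over included genes of this contrast only.

    ``prior_df`` overrides the estimated prior df (0 recovers the ordinary
    pooled two-sample t; infinity gives the common-variance z-form).
    """
    config = config or Config()
    group_a, group_b = contrast
    design.validate_against(matrix)
    samples_a = design.samples_in_group(str(group_a), column=group_column)
    samples_b = design.samples_in_group(str(group_b), column=group_column)
    for label, smp in ((group_a, samples_a), (group_b, samples_b)):
        if len(smp) == 0:
            raise ValidationError(f"contrast group {label!r} has no samples")
    n1, n2 = len(samples_a), len(samples_b)
    df = n1 + n2 - 2
    if df < 1:
        raise ValidationError(
            f"groups {group_a!r} (n={n1}) and {group_b!r} (n={n2}): "
            "no residual degrees of freedom for variance pooling"
        )
    comparison_samples = samples_a + samples_b
    included = _included_genes(matrix.subset_samples(comparison_samples),
                               comparison_samples, config)
    inc_mask = matrix.values.index.isin(included)

    xa = matrix.values[samples_a].to_numpy()
    xb = matrix.values[samples_b].to_numpy()
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    effect = mean_a - mean_b
    c_factor = 1.0 / n1 + 1.0 / n2

    table, hyper = _moderated_table(matrix.values.index, inc_mask, mean_a, mean_b,
                                    effect, s2, df, c_factor, prior_df, prior_var)
    result = DEResult(table, contrast=f"{group_a}/{group_b}",
                      group_a=str(group_a), group_b=str(group_b))
    result.ebayes = hyper
    return result


def interaction_fit(matrix: ExpressionMatrix, design: SampleTable,
                    config: Config | None = None,
                    prior_df: float | None = None,
                    prior_var: float | None = None) -> DEResult:
    """Genotype-by-age interaction from the two-factor cell-means model.

    The interaction effect is the difference of aging log2FCs:
    (old - young in KO) - (old - young in WT); its moderated t uses the
    variance pooled within the four design cells (df = N - 4). ``mean_a`` and
    ``mean_b`` report the per-genotype aging log2FCs (KO and WT).
    """
    config = config or Config()
    design.validate_against(matrix)
    design.validate_two_by_two()
    cells = {}
    for gt in ("WT", "KO"):
        for age in ("young", "old"):
            mask = (design.table["genotype"].astype(str) == gt) & \
                   (design.table["age"].astype(str) == age)
            smp = list(design.table.index[mask])
            if not smp:
                raise ValidationError(f"empty design cell genotype={gt}, age={age}")
            cells[(gt, age)] = smp
    all_samples = [s for smp in cells.values() for s in smp]
    n_total = len(all_samples)
    df = n_total - 4
    if df < 1:
        raise ValidationError("interaction fit requires residual df >= 1 (N > 4)")
    included = _included_genes(matrix.subset_samples(all_samples), all_samples, config)
    inc_mask = matrix.values.index.isin(included)

    means = {}
    ss = np.zeros(matrix.shape[0])
    c_factor = 0.0
    for key, smp in cells.items():
        x = matrix.values[smp].to_numpy()
        m = x.mean(axis=1)
        means[key] = m
        ss += ((x - m[:, None]) ** 2).sum(axis=1)
        c_factor += 1.0 / len(smp)
    s2 = ss / df
    aging_ko = means[("KO", "old")] - means[("KO", "young")]
    aging_wt = means[("WT", "old")] - means[("WT", "young")]
    effect = aging_ko - aging_wt

    table, hyper = _moderated_table(matrix.values.index, inc_mask, aging_ko, aging_wt,
                                    effect, s2, df, c_factor, prior_df, prior_var)
    result = DEResult(table, contrast="genotypexage", group_a="KO-aging", group_b="WT-aging")
    result.ebayes = hyper
    return result


def call_degs(de: DEResult, fdr: float = 0.10, fc_up: float = 1.50,
              fc_down: float = 0.67) -> tuple[list[str], list[str]]:
    """Up/down differentially expressed genes at strict FDR and FC thresholds.

    up: FDR < fdr and FC > fc_up; down: FDR < fdr and FC < fc_down. Genes
    excluded by the detection filter are never called.
    """
    sub = de.included
    sig = sub["fdr"] < fdr
    up = list(sub.index[sig & (sub["fc"] > fc_up)])
    down = list(sub.index[sig & (sub["fc"] < fc_down)])
    return up, down
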