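"""Two-stage derivation of population signature gene sets from a compendium.

For each cell population, a one-vs-rest moderated-t contrast is fit against
the pooled remaining samples. Signature genes are then selected in stages:
keep fold-change-concordant genes (FC > 1 for "up", FC < 1 for "down"), keep
the ``n_p`` (default 150) of these with lowest p-value, and finally keep the
``n_sig`` (default 100) of those with the most extreme fold change. The same
path serves tissue signatures (e.g. adipose-vs-liver) and the
decreased-expression variant used for treatment contrasts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from sigshift.data import (
    Config,
    DEResult,
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
    SignatureSet,
    ValidationError,
)
from sigshift.diffexpr import call_degs, fit_moderated

logger = logging.getLogger("sigshift")

REST_LABEL = "__rest__"


def one_vs_rest(matrix: ExpressionMatrix, design: SampleTable, population: str,
                config: Config | None = None) -> DEResult:
    """Moderated-t contrast of one population versus all other samples pooled."""
    config = config or Config()
    if "population" not in design.table.columns:
        raise ValidationError("compendium sample table requires a 'population' column")
    pops = design.table["population"].astype(str)
    if str(population) not in set(pops):
        raise ValidationError(f"unknown population {population!r}")
    labels = np.where(pops == str(population), str(population), REST_LABEL)
    ovr = SampleTable(pd.DataFrame({"group": labels}, index=design.table.index))
    n_pop = int((labels == str(population)).sum())
    if n_pop < 2:
        raise ValidationError(f"population {population!r} has fewer than 2 replicates")
    if n_pop == len(labels):
        raise ValidationError(f"population {population!r} leaves no rest samples")
    return fit_moderated(matrix, ovr, (str(population), REST_LABEL), config=config)


def select_signature(de: DEResult, n_p: int = 150, n_sig: int = 100,
                     direction: str = "up", name: str | None = None,
                     candidates=None) -> SignatureSet:
    """Staged signature selection from a one-vs-rest (or two-group) contrast.

    Stage 1 keeps fold-change-concordant genes (FC > 1 up / FC < 1 down),
    optionally restricted to a pre-filtered candidate set; stage 2 keeps the
    ``n_p`` lowest-p of these; stage 3 keeps the ``n_sig`` with most extreme
    FC. Ties are broken deterministically: at the p cutoff by larger |log2FC|
    then gene id; at the FC cutoff by smaller p then gene id. If fewer than
    ``n_sig`` genes survive stage 1 the set is returned short and flagged.
    """
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    if n_sig > n_p:
        raise ValidationError(f"n_sig ({n_sig}) must be <= n_p ({n_p})")
    name = name if name is not None else de.group_a
    sub = de.included.copy()
    if candidates is not None:
        sub = sub.loc[sub.index.intersection(pd.Index([str(g) for g in candidates]))]
    if direction == "up":
        stage1 = sub.loc[sub["fc"] > 1.0]
    else:
        stage1 = sub.loc[sub["fc"] < 1.0]
    if len(stage1) == 0:
        logger.warning("signature %r: no fold-change-concordant genes; empty set", name)
        return SignatureSet(name, [], stage1[["fc", "p"]], direction=direction,
                            n_p=n_p, n_sig=n_sig, truncated=True,
                            stage1_n=0, stage2_n=0)

    stage1 = stage1.assign(_absl2=stage1["log2fc"].abs())
    stage2 = stage1.reset_index(names="gene").sort_values(
        ["p", "_absl2", "gene"], ascending=[True, False, True], kind="mergesort"
    ).head(n_p)
    fc_ascending = direction == "down"
    stage3 = stage2.sort_values(
        ["fc", "p", "gene"], ascending=[fc_ascending, True, True], kind="mergesort"
    ).head(n_sig)
    genes = list(stage3["gene"])
    truncated = len(genes) < n_sig
    if truncated:
        logger.warning("signature %r: only %d candidates survived stage 1 (wanted %d)",
                       name, len(genes), n_sig)
    stats = sub.loc[genes, ["fc", "p", "log2fc"]]
    return SignatureSet(name, genes, stats, direction=direction, n_p=n_p,
                        n_sig=n_sig, truncated=truncated,
                        stage1_n=len(stage1), stage2_n=len(stage2))


def derive_all(matrix: ExpressionMatrix, design: SampleTable,
               config: Config | None = None) -> tuple[dict[str, SignatureSet], pd.DataFrame]:
    """One signature set per compendium population, plus a DEG-count summary.

    Overlapping membership between populations is permitted. The summary table
    reports, per population, the number of one-vs-rest DEGs with elevated
    expression at the standard thresholds (FDR < 0.10 with FC > 1.50).
    """
    config = config or Config()
    if "population" not in design.table.columns:
        raise ValidationError("compendium sample table requires a 'population' column")
    populations = sorted(set(design.table["population"].astype(str)))
    signatures: dict[str, SignatureSet] = {}
    rows = []
    for pop in populations:
        de = one_vs_rest(matrix, design, pop, config=config)
        up, _ = call_degs(de, fdr=config.fdr, fc_up=config.fc_up, fc_down=config.fc_down)
        sig = select_signature(de, n_p=config.n_p, n_sig=config.n_sig,
                               direction="up", name=pop)
        signatures[pop] = sig
        rows.append({"population": pop, "n_up_degs": len(up),
                     "n_signature": len(sig), "truncated": sig.truncated})
    summary = pd.DataFrame(rows)
    return signatures, summary


def signatures_to_collection(signatures: dict[str, SignatureSet]) -> GeneSetCollection:
    """Signature sets as a GMT-writable collection (derivation noted in the description)."""
    sets = {name: list(sig.genes) for name, sig in signatures.items() if len(sig)}
    descriptions = {
        name: f"direction={sig.direction};n_p={sig.n_p};n_sig={sig.n_sig}"
        for name, sig in signatures.items() if len(sig)
    }
    return GeneSetCollection(sets, descriptions)
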