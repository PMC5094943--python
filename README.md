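# sigshift

Cell-population signature derivation and directional signature-enrichment
statistics for bulk expression studies.

## The problem

Bulk tissue expression profiles mix the transcriptomes of resident cells with
those of infiltrating cell populations. In aging studies this matters
directly: "inflammaging" shows up in a liver or skin microarray not as a
single gene switching on, but as the coordinated, often modest elevation of
hundreds of transcripts specifically expressed by immune cells that have
accumulated in the tissue. Asking whether a genotype blunts or enhances this
process therefore requires (i) a per-gene differential expression analysis
that is stable at small sample sizes, (ii) a way to define which genes are
*specifically* expressed by each cell population or tissue, and (iii)
statistics that detect a coordinated directional shift of such a gene set
against the genome-wide background.

`sigshift` implements that full chain for a 2×2 genotype-by-age design
(genotype ∈ {WT, KO}, age ∈ {young, old}), together with synthetic-data
generators that plant known ground truth at every stage, so each statistical
claim the pipeline makes can be verified by recovery experiments.

## The methods at its core

**Moderated differential expression.** For each gene g, a linear model on
log2 intensities gives an effect estimate (log2 fold change) and a residual
variance s²_g with d_g degrees of freedom. Gene-wise variances are shrunk
toward a prior by empirical Bayes:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),   t_g = log2FC_g / (s̃_g·c),

with t_g referred to a t distribution on d₀ + d_g df. The hyperparameters
(d₀, s₀²) are estimated by closed-form moment matching on log s²_g using
digamma/trigamma identities. Genes are pre-filtered by an above-background
detection rule (signed-rank test of perfect-match vs mismatch probe
intensities; a gene must be detected in ≥ 1/3 of the samples in a
comparison), p-values are Benjamini–Hochberg adjusted per contrast, and DEGs
are called at FDR < 0.10 with linear FC > 1.50 or < 0.67.

**Two-stage signature selection.** For each population in a labeled
reference compendium, a one-vs-rest moderated contrast is fit; signature
genes are then chosen by keeping fold-change-concordant genes (FC > 1), the
150 of these with lowest p, and finally the 100 of those with highest FC
(the decreased-expression variant mirrors this with FC < 1 / lowest FC), so
every population contributes a signature of equal size.

**Directional enrichment.** Given a fold-change vector for one comparison
and a signature S:

* *rank-sum bias*: Wilcoxon rank sum test of log2FCs, S vs background,
  reported as signed Log10P (−log10 p, positive when the signature median
  exceeds the background median);
* *direction counts*: Fisher's exact test on {S, background} × {FC > 1,
  FC ≤ 1}, with the middle 95% of the hypergeometric null for the up-count;
* *cumulative-overlap AUC*: genes ranked by the comparison statistic; the
  area under the overlap curve equals the Wilcoxon–Mann–Whitney U/(n₁n₂), so
  0.5 is the no-enrichment diagonal.

The package also provides the supporting statistics used around these: exact
small-sample rank tests, hypergeometric over-representation (with an
optional parent/child conditioning pass), Spearman rank correlation of
genome-wide fold changes, protected Fisher's-LSD compact letter displays,
and 2^−ΔΔCt relative expression for qPCR validation.

## Worked example

Generate the scenario in which a B-cell-like population infiltrates old-KO
livers only, derive signatures from the companion compendium, and rank
populations by their directional bias in the old-KO/old-WT comparison:

```python
from sigshift.synthetic import make_preset
from sigshift.signatures import derive_all
from sigshift.diffexpr import fit_moderated, call_degs
from sigshift.enrichment import rank_signatures

cm, cd, sm, sd, truth = make_preset("fig5", seed=1)
sigs, summary = derive_all(cm, cd)            # 5 signatures of 100 genes
de = fit_moderated(sm, sd, ("old-KO", "old-WT"))
up, down = call_degs(de)
print(f"{de.contrast}: {len(de.included)} genes included, {len(up)} up, {len(down)} down")
for r in rank_signatures(de.fc_vector(), sigs)[:3]:
    print(f"{r.signature}: mean FC {r.mean_fc:.2f}, signed Log10P {r.signed_log10p:+.1f}, "
          f"{r.n_up}/{r.n_used} up (null band {r.null_band[0]}-{r.null_band[1]}), AUC {r.auc:.3f}")
```

which prints

```
old-KO/old-WT: 1704 genes included, 70 up, 2 down
pop1: mean FC 1.51, signed Log10P +51.5, 99/100 up (null band 91-99), AUC 0.952
pop2: mean FC 1.30, signed Log10P +23.6, 98/100 up (null band 91-99), AUC 0.803
pop4: mean FC 1.16, signed Log10P -1.0, 95/100 up (null band 91-99), AUC 0.449
```

`pop1` is the planted B-cell-like population: its 100 signature genes sit at
a mean FC of 1.51 in old-KO vs old-WT, 99 of them are elevated (above the
91–99 band expected by chance given the background), and they concentrate at
the top of the KO-increased ranking (AUC 0.95). The planted T-cell-like
population (`pop2`) shows the same pattern more weakly, and an unplanted
population (`pop4`) sits on the diagonal. The same pipeline is available
from the shell (`sigshift simulate | de | signatures | enrich | run | qpcr`).

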