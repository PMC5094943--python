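# Methods

This note documents the statistical models, conventions and design choices
behind `sigshift`, in the order the pipeline applies them, together with
what the synthetic-data generators do and do not emulate.

## Data model and conventions

All expression values are log2-scale intensities; the package never
normalizes raw data (background subtraction, quantile normalization and
probe summarization are upstream concerns and out of scope). Linear fold
changes are always 2^(difference of log2 group means), and DEG thresholds
(FC > 1.50, FC < 0.67, FDR < 0.10) are applied as strict inequalities on
that linear scale. Gene identifiers are matched as exact case-sensitive
strings; no alias resolution is attempted. Result tables round-trip through
TSV at 12 significant digits with deterministic row and column order.

## Detection filtering

A probe set is called above-background in a sample when a one-sided
Wilcoxon signed-rank test of perfect-match minus mismatch intensities gives
p < 0.05; a gene is detected if at least one of its probe sets is. A gene
enters a differential expression comparison only if it is detected in at
least one third of the samples involved in that comparison. Because n/3 is
not an integer for most designs, the rule is: included iff detected count ≥
⌈n/3⌉ (equivalently, count ≥ n/3 exactly when 3 | n); the fraction is
configurable. Filtered genes are retained in result tables as excluded rows
with missing statistics rather than dropped, so every output table has one
row per input gene.

## Moderated differential expression

Each two-group contrast is fit as an independent gene-wise two-sample model
on log2 values (pooled variance, d = n₁+n₂−2 residual df), rather than one
omnibus model across all four groups; this keeps the detection filter
per-comparison and makes contrasts independent of which other groups are in
the file. The genotype-by-age interaction is a separate two-factor
cell-means fit: the interaction effect is the difference of the two aging
log2FCs, (old−young in KO) − (old−young in WT), with variance pooled within
the four cells (d = N−4) and standard-error factor √(Σ 1/n_cell).

Variance moderation follows the canonical empirical-Bayes formulation:
given gene variances s²_g ~ s₀²·χ²_d/d scaled by an inverse-chi-square
prior with d₀ df, the posterior variance is the convex combination
s̃²_g = (d₀s₀² + d·s²_g)/(d₀+d) and t_g = log2FC_g/(s̃_g·c) has d₀+d df
under the null. The hyperparameters are estimated by moment matching on
z_g = log s²_g: after centering by digamma(d/2) − log(d/2), the excess
variance of z over trigamma(d/2) identifies d₀ through a trigamma
inversion (Newton iteration), and the mean identifies s₀². When the excess
variance is non-positive, d₀ = ∞ and all genes share s₀². The
implementation agrees with the Bioconductor limma reference to ~1e-14 on a
common fixture (verified in the test suite via Rscript), and `prior_df`
can be forced to 0 (ordinary pooled t) or ∞ (common-variance z) for
diagnostic use.

Benjamini–Hochberg adjustment is applied within each contrast over included
genes only; the package takes per-contrast adjustment as its convention
(adjusting across pooled contrasts is not supported).

## Signature selection

One-vs-rest contrasts use the same moderated machinery, with the "rest"
samples pooled into a single group. Selection is staged: (1) keep genes with
FC concordant to the requested direction (FC > 1 for up, FC < 1 for down),
optionally intersected with a caller-supplied candidate list (used when the
contrast was pre-filtered to DEGs); (2) keep the n_p = 150 lowest-p genes;
(3) keep the n_sig = 100 most extreme by FC. Ties are broken
deterministically — at the p cutoff by larger |log2FC| then lexicographic
gene id, at the FC cutoff by smaller p then gene id — because p-value and
FC ties are common in discrete or small-sample settings and reproducibility
requires a total order. If fewer than n_sig genes survive stage 1, the
signature is returned short and flagged rather than padded. The selected
set is always a subset of the n_p lowest-p concordant genes, selection is
idempotent, and output is invariant to sample order.

## Enrichment statistics

The background for every signature statistic is "all measured genes not in
the signature" within the comparison at hand, not an external universe.
Signature genes absent from the fold-change vector are dropped with a
logged count; they are never imputed.

*Rank-sum bias.* The two-sided Wilcoxon rank sum test compares signature vs
background log2FCs; there is a single code path (the kernel's
`rank_sum_test`) shared by the enrichment layer. The signed Log10P is
−log10(p) carrying the sign of (signature median log2FC − background median
log2FC); p = 0 underflow is clamped at 1e-300 and logged.

*Direction counts.* Directions dichotomize at linear FC = 1, with ties
counted as "down" (configurable consequence of using FC > 1 strictly). The
2×2 exact test conditions on margins; the reported null band is the central
95% of the hypergeometric distribution of the signature's up-count given
the background proportion.

*Overlap AUC.* Genes are ranked by the comparison statistic (descending
log2FC by default). The display curve is cumulative signature count vs rank
normalized to the unit square (raw counts are also exposed); the AUC is the
trapezoidal area of the overlap-vs-background step curve with tied
statistics grouped into diagonal segments, which is algebraically the
mid-rank Wilcoxon–Mann–Whitney U/(n₁n₂). AUC − 0.5 is the excess over the
diagonal; its significance is the same rank-sum p as the bias test.

## Statistical kernel conventions

Rank-based tests use mid-ranks throughout. The rank-sum test enumerates the
exact null when the combined n ≤ 12 and there are no ties, and otherwise
uses a normal approximation with tie-corrected variance and a 0.5
continuity correction; the signed-rank test enumerates all 2^n sign
patterns for n ≤ 15 (zeros dropped first). These switch points keep
desk-scale analyses exact while remaining fast; every result carries a
method tag naming the path taken. Fisher's exact test enumerates the
hypergeometric support; the two-sided p sums probabilities of tables no
more probable than the observed one (the convention of mainstream
implementations; doubling conventions differ and are not used). Degenerate
inputs (all-tied samples, empty margins, all-zero differences) return p = 1
with a degenerate method tag rather than erroring, except where no test is
possible at all.

Over-representation of gene sets uses the plain upper-tail hypergeometric
test. An optional parent→children map enables a one-pass conditional
variant: children are tested first and hits belonging to significant
children (p < α) are removed from the parent before it is tested. This is
the in-scope analogue of ontology-conditional testing; full DAG-aware
conditioning would require the ontology structure itself, which the package
deliberately does not model.

Fisher's LSD is implemented in its protected form: pairwise t tests use the
one-way ANOVA pooled MSE and its df, and when the omnibus F test is not
significant at α all groups collapse onto a single letter (an option
disables the gate). Letters are assigned by insert-and-absorb, which
guarantees two groups share a letter iff their pairwise p ≥ α. For qPCR
data the ANOVA runs on the ΔCt scale by default — Ct differences are
approximately variance-stabilized, while 2^−ΔΔCt is right-skewed — with
the relative-expression scale available as an option. Relative expression
is normalized so the calibrator group's arithmetic mean is exactly 1.

## Synthetic data: what it emulates, and what it does not

The generators produce (i) a labeled compendium (default 5 populations × 3
replicates, 100 planted markers per population at +2 log2), emulating a
reference atlas of sorted cell populations at reduced scale; (ii) a 2×2
study with the default cell sizes 5/5/6/8 (young-WT/young-KO/old-WT/old-KO)
carrying planted aging, genotype and interaction effects with alternating
signs; and (iii) small two-group contrasts (n = 3/group) with planted
up/down genes, for the tissue- and treatment-signature variants.

Baselines come from a two-component mixture — expressed genes N(7, 1.5²)
and a 20% near-background component N(3, 0.5²) — so the detection filter
has genes to exclude; simulated detection calls hit expressed genes at
99.5% and near-background genes at 25% per sample. Gene variances are
scaled-inverse-chi-square with d₀ = 4 and s₀² = 0.05 (typical residual SDs
~0.15–0.35 log2 units), precisely the model under which the moderation
machinery is well-specified — this is a deliberate best-case coupling, and
tests on this data demonstrate correctness of the estimator, not
robustness to prior misspecification. A fixed common SD can be forced for
power experiments.

Infiltration is additive on the linear scale: each contaminated sample is
2^(resident log2 profile) + Σ_pop w·2^(population marker profile),
re-logged. This is the mechanism a physical cell mixture implies; it makes
marker fold changes respond sub-linearly in w and — importantly — shifts
*every* gene in contaminated samples upward slightly, so rank-based
signature-vs-background statistics (which are insensitive to global
shifts) are the appropriate readout, while raw direction counts sit on an
elevated background. The preset weights (`fig5`: B-like 0.12 and T-like
0.05 in old-KO only, monocyte-like 0.08 in old samples of both genotypes;
`fig6`: adipose-like 0.02/0.02/0.15/0.05 across the four cells) are
synthetic calibrations chosen to reproduce the qualitative study scenarios
— age-dependent immune infiltration, a genotype-restricted lymphocyte
signal, and an age-related adipose signal blunted in the knockout — at
signature fold changes in the realistic 1.1–1.6 range; they are not
estimates of any real tissue composition.

What the generators do not emulate: probe-level structure, batch and
platform effects, inter-gene correlation beyond the shared infiltration
signal, compositional renormalization of mixtures, and gene-gene dependence
of variances. Passing recovery tests on this data therefore shows the
pipeline detects the planted mechanism under its own model assumptions; it
does not certify behavior under platform artifacts or correlated noise.

## Problem sizes and determinism

Recovery and calibration experiments run at reduced scale chosen to make
their conclusions stable: compendia of 2,000–3,000 genes, null calibration
at 5,000–10,000 genes with 2,000 random signatures, and 20 independent
seeds for the scenario-recovery and FDR experiments. All generators are
driven by `numpy.random.default_rng` from a single integer seed; identical
spec + seed reproduces outputs byte-for-byte after serialization, and the
pipeline manifest records SHA-256 digests of every table so a run can be
verified post hoc.

## Known limitations

* Contrasts are two-group fits; covariates, array weights and
  correlation-aware gene-set tests (camera/GSEA-style permutation methods)
  are out of scope.
* The interaction test reports only the 2×2 interaction coefficient; higher
  factorial designs are not supported.
* The conditional over-representation pass is a single child-to-parent
  sweep, not a full ontology decomposition.
* Signature derivation assumes the compendium and the study share an
  identifier space; no cross-platform mapping is provided.
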