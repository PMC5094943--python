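"""Synthetic expression data with planted ground truth.

Three generators cover every input the pipeline consumes:

* :func:`make_compendium` — a multi-population reference compendium with
  population-specific marker genes (the signature-derivation substrate);
* :func:`make_study` — a 2x2 genotype-by-age study with gene-wise aging,
  genotype and interaction effects plus additive cell-infiltration
  contamination (the enrichment substrate);
* :func:`make_two_group` — two-group tissue/treatment contrasts with planted
  up/down genes (the signature-variant substrate).

Log2 baselines come from a two-component mixture (expressed vs
near-background) so the detection filter has genes to exclude. Gene-wise
noise variances are drawn from a scaled inverse chi-square prior (d0, s0^2),
the model under which the empirical-Bayes moment estimator is well-specified.
Infiltration is additive on the linear scale — a mixture of the resident
expression and a weighted cell-type profile — then re-logged, so signature
gene fold changes respond sub-linearly, as a physical cell mixture would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from sigshift.data import (
    ExpressionMatrix,
    SampleTable,
    SyntheticTruth,
    ValidationError,
)

logger = logging.getLogger("sigshift")

STUDY_GROUPS = ("young-WT", "young-KO", "old-WT", "old-KO")

CONTRASTS = {
    "young-KO/young-WT": ("young-KO", "young-WT"),
    "old-KO/old-WT": ("old-KO", "old-WT"),
    "old-WT/young-WT": ("old-WT", "young-WT"),
    "old-KO/young-KO": ("old-KO", "young-KO"),
}


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic generators, with study-scale defaults.

    The study design cell sizes default to young-WT 5, young-KO 5, old-WT 6,
    old-KO 8. Gene variances are scaled-inverse-chi-square(prior_df,
    prior_var); set ``sigma`` to force a single common noise SD instead.
    Effects are log2 units; planted effect genes alternate sign unless
    ``signed_effects`` is False.
    """

    n_genes: int = 2000
    seed: int = 0
    # log2 baseline mixture: expressed vs near-background
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    background_mean: float = 3.0
    background_sd: float = 0.5
    background_fraction: float = 0.2
    # gene-wise variance prior (inverse-gamma / scaled inverse chi-square)
    prior_df: float = 4.0
    prior_var: float = 0.05
    sigma: float | None = None
    # compendium structure
    n_populations: int = 5
    replicates: int = 3
    markers_per_population: int = 100
    marker_effect: float = 2.0
    allow_marker_overlap: bool = False
    # 2x2 study structure
    cell_sizes: dict = field(default_factory=lambda: {
        "young-WT": 5, "young-KO": 5, "old-WT": 6, "old-KO": 8})
    n_aging: int = 0
    aging_effect: float = 1.0
    n_genotype: int = 0
    genotype_effect: float = 1.0
    n_interaction: int = 0
    interaction_effect: float = 0.0
    signed_effects: bool = True
    # infiltration: population -> {group label -> linear mixing weight}
    infiltration: dict = field(default_factory=dict)
    # two-group structure
    n_per_group: int = 3
    n_up: int = 0
    n_down: int = 0
    two_group_effect: float = 1.5
    # detection simulation
    with_detection: bool = False
    background_detect_rate: float = 0.25
    expressed_detect_rate: float = 0.995

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_populations <= 0 or self.replicates <= 0:
            raise ValidationError("all generator sizes must be positive")
        if any(n <= 0 for n in self.cell_sizes.values()):
            raise ValidationError("all design cells must be non-empty")
        for pop, weights in self.infiltration.items():
            for grp, w in weights.items():
                if w < 0:
                    raise ValidationError(
                        f"negative infiltration weight {w} for {pop!r} in {grp!r}")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def _baselines(spec: GeneratorSpec, rng: np.random.Generator):
    n_bg = int(round(spec.background_fraction * spec.n_genes))
    is_background = np.zeros(spec.n_genes, dtype=bool)
    # deterministic placement: the trailing block of genes is near-background
    is_background[spec.n_genes - n_bg:] = True
    base = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    base[is_background] = rng.normal(spec.background_mean, spec.background_sd, size=n_bg)
    return base, is_background


def _gene_sds(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.sigma is not None:
        return np.full(spec.n_genes, float(spec.sigma))
    chi2 = rng.chisquare(spec.prior_df, size=spec.n_genes)
    var = spec.prior_df * spec.prior_var / chi2
    return np.sqrt(var)


def _effect_signs(k: int, signed: bool) -> np.ndarray:
    if not signed:
        return np.ones(k)
    return np.where(np.arange(k) % 2 == 0, 1.0, -1.0)


def _marker_blocks(spec: GeneratorSpec, genes: list[str], is_background: np.ndarray):
    expressed = [g for g, bg in zip(genes, is_background) if not bg]
    need = spec.markers_per_population * spec.n_populations
    if not spec.allow_marker_overlap and need > len(expressed):
        raise ValidationError(
            f"{need} marker genes requested but only {len(expressed)} expressed "
            "genes available (declare allow_marker_overlap to reuse genes)"
        )
    blocks = {}
    for k in range(spec.n_populations):
        pop = f"pop{k + 1}"
        if spec.allow_marker_overlap:
            start = (k * spec.markers_per_population) % len(expressed)
            idx = [(start + j) % len(expressed) for j in range(spec.markers_per_population)]
            blocks[pop] = [expressed[j] for j in idx]
        else:
            blocks[pop] = expressed[k * spec.markers_per_population:
                                    (k + 1) * spec.markers_per_population]
    return blocks


def make_compendium(spec: GeneratorSpec):
    """Labeled reference compendium with planted population markers.

    Each population's markers are shifted up by ``marker_effect`` log2 units
    relative to every other population. Returns ``(ExpressionMatrix,
    SampleTable, SyntheticTruth)``; truth lists the marker genes per
    population.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    base, is_background = _baselines(spec, rng)
    sds = _gene_sds(spec, rng)
    blocks = _marker_blocks(spec, genes, is_background)
    gene_pos = {g: i for i, g in enumerate(genes)}

    sample_ids, pops = [], []
    columns = []
    for pop in blocks:
        mean = base.copy()
        mean[[gene_pos[g] for g in blocks[pop]]] += spec.marker_effect
        for r in range(spec.replicates):
            sample_ids.append(f"{pop}_r{r + 1}")
            pops.append(pop)
            columns.append(mean + rng.normal(0.0, sds))
    values = np.column_stack(columns)
    matrix = ExpressionMatrix(values, gene_ids=genes, sample_ids=sample_ids)
    design = SampleTable(pd.DataFrame(
        {"population": pops, "group": pops}, index=pd.Index(sample_ids, name="sample_id")))
    truth = SyntheticTruth(marker_genes={p: list(g) for p, g in blocks.items()})
    return matrix, design, truth


def _study_effect_blocks(spec: GeneratorSpec, genes: list[str],
                         is_background: np.ndarray, reserved: set[str]):
    """Disjoint aging / genotype / interaction gene blocks among expressed genes."""
    pool = [g for g, bg in zip(genes, is_background) if not bg and g not in reserved]
    need = spec.n_aging + spec.n_genotype + spec.n_interaction
    if need > len(pool):
        raise ValidationError(
            f"{need} effect genes requested but only {len(pool)} unreserved "
            "expressed genes available"
        )
    aging = pool[:spec.n_aging]
    genotype = pool[spec.n_aging:spec.n_aging + spec.n_genotype]
    interaction = pool[spec.n_aging + spec.n_genotype:need]
    return aging, genotype, interaction


def make_study(spec: GeneratorSpec, marker_genes: dict[str, list[str]] | None = None):
    """2x2 genotype-by-age study with effects and infiltration contamination.

    Planted structure: ``n_aging`` genes shifted in old samples of both
    genotypes, ``n_genotype`` genes shifted in KO samples of both ages,
    ``n_interaction`` genes shifted in old-KO only (a pure interaction), and
    additive infiltration of cell-population profiles per the
    ``spec.infiltration`` weights. ``marker_genes`` supplies the population
    marker memberships (normally the companion compendium's truth); marker
    profiles are the study baseline plus ``marker_effect`` on those genes.

    Returns ``(ExpressionMatrix, SampleTable, SyntheticTruth)``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = _gene_ids(spec.n_genes)
    base, is_background = _baselines(spec, rng)
    sds = _gene_sds(spec, rng)
    gene_pos = {g: i for i, g in enumerate(genes)}

    if spec.infiltration and marker_genes is None:
        raise ValidationError("infiltration requested without marker gene sets")
    marker_genes = marker_genes or {}
    for pop in spec.infiltration:
        if pop not in marker_genes:
            raise ValidationError(f"infiltration references unknown population {pop!r}")
    reserved = {g for gl in marker_genes.values() for g in gl}

    aging, genotype, interaction = _study_effect_blocks(spec, genes, is_background, reserved)
    aging_eff = dict(zip(aging, spec.aging_effect * _effect_signs(len(aging), spec.signed_effects)))
    geno_eff = dict(zip(genotype, spec.genotype_effect * _effect_signs(len(genotype), spec.signed_effects)))
    inter_eff = dict(zip(interaction, spec.interaction_effect * _effect_signs(len(interaction), spec.signed_effects)))

    profiles = {}
    for pop, gl in marker_genes.items():
        prof = base.copy()
        prof[[gene_pos[g] for g in gl]] += spec.marker_effect
        profiles[pop] = 2.0 ** prof

    sample_ids, groups, genos, ages = [], [], [], []
    columns = []
    for group in STUDY_GROUPS:
        n = spec.cell_sizes.get(group, 0)
        age, geno = group.split("-")
        mean = base.copy()
        if age == "old":
            for g, e in aging_eff.items():
                mean[gene_pos[g]] += e
        if geno == "KO":
            for g, e in geno_eff.items():
                mean[gene_pos[g]] += e
        if age == "old" and geno == "KO":
            for g, e in inter_eff.items():
                mean[gene_pos[g]] += e
        for r in range(n):
            sid = f"{group}_{r + 1}"
            sample_ids.append(sid)
            groups.append(group)
            genos.append(geno)
            ages.append(age)
            linear = 2.0 ** (mean + rng.normal(0.0, sds))
            for pop, weights in spec.infiltration.items():
                w = weights.get(group, 0.0)
                if w > 0:
                    linear = linear + w * profiles[pop]
            columns.append(np.log2(linear))
    values = np.column_stack(columns)

    detection = None
    if spec.with_detection:
        rate = np.where(is_background, spec.background_detect_rate,
                        spec.expressed_detect_rate)
        detection = rng.random((spec.n_genes, len(sample_ids))) < rate[:, None]

    matrix = ExpressionMatrix(values, gene_ids=genes, sample_ids=sample_ids,
                              detection=detection)
    design = SampleTable(pd.DataFrame(
        {"group": groups, "genotype": genos, "age": ages},
        index=pd.Index(sample_ids, name="sample_id")))
    design.validate_two_by_two()

    de_genes = {name: {} for name in CONTRASTS}
    for g, e in geno_eff.items():
        de_genes["young-KO/young-WT"][g] = e
        de_genes["old-KO/old-WT"][g] = e
    for g, e in inter_eff.items():
        de_genes["old-KO/old-WT"][g] = de_genes["old-KO/old-WT"].get(g, 0.0) + e
    for g, e in aging_eff.items():
        de_genes["old-WT/young-WT"][g] = e
        de_genes["old-KO/young-KO"][g] = e
    for g, e in inter_eff.items():
        de_genes["old-KO/young-KO"][g] = de_genes["old-KO/young-KO"].get(g, 0.0) + e
    truth = SyntheticTruth(
        marker_genes={p: list(g) for p, g in marker_genes.items()},
        de_genes={k: v for k, v in de_genes.items() if v},
        interaction_genes=dict(inter_eff),
        infiltration={p: dict(w) for p, w in spec.infiltration.items()},
    )
    return matrix, design, truth


def make_two_group(spec: GeneratorSpec, labels: tuple[str, str] = ("A", "B")):
    """Two-group contrast with planted up/down genes (effect applied to group A).

    Emulates small tissue/treatment comparisons (n = 3 per group by default):
    ``n_up`` genes shifted up and ``n_down`` genes shifted down in the first
    group by ``two_group_effect`` log2 units.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = _gene_ids(spec.n_genes)
    base, is_background = _baselines(spec, rng)
    sds = _gene_sds(spec, rng)
    expressed = [g for g, bg in zip(genes, is_background) if not bg]
    if spec.n_up + spec.n_down > len(expressed):
        raise ValidationError("more planted genes than expressed genes")
    up = expressed[:spec.n_up]
    down = expressed[spec.n_up:spec.n_up + spec.n_down]
    gene_pos = {g: i for i, g in enumerate(genes)}

    a, b = labels
    mean_a = base.copy()
    for g in up:
        mean_a[gene_pos[g]] += spec.two_group_effect
    for g in down:
        mean_a[gene_pos[g]] -= spec.two_group_effect

    sample_ids, groups, columns = [], [], []
    for label, mean in ((a, mean_a), (b, base)):
        for r in range(spec.n_per_group):
            sample_ids.append(f"{label}_{r + 1}")
            groups.append(str(label))
            columns.append(mean + rng.normal(0.0, sds))
    matrix = ExpressionMatrix(np.column_stack(columns), gene_ids=genes,
                              sample_ids=sample_ids)
    design = SampleTable(pd.DataFrame(
        {"group": groups}, index=pd.Index(sample_ids, name="sample_id")))
    contrast = f"{a}/{b}"
    effects = {g: spec.two_group_effect for g in up}
    effects.update({g: -spec.two_group_effect for g in down})
    truth = SyntheticTruth(de_genes={contrast: effects})
    return matrix, design, truth


# ---------------------------------------------------------------------------
# presets: the qualitative scenarios of the study, with known truth

def preset_spec(preset: str, seed: int = 0) -> GeneratorSpec:
    """Generator settings for the named scenario.

    ``null``: no planted structure. ``fig5``: B-cell-like infiltration planted
    only in old-KO samples (with monocyte-like infiltration in old samples of
    both genotypes), the scenario where the old-KO/old-WT comparison should
    rank the B-like population first. ``fig6``: an adipose-tissue-like signal
    stronger in old-WT than old-KO, the scenario where the signature's aging
    overlap AUC is larger in WT than in KO.
    """
    common = dict(n_genes=2000, seed=seed, n_populations=5,
                  markers_per_population=100, marker_effect=2.0, replicates=3)
    if preset == "null":
        return GeneratorSpec(**common)
    if preset == "fig5":
        return GeneratorSpec(**common, infiltration={
            "pop1": {"old-KO": 0.12},                      # B-cell-like: old KO only
            "pop2": {"old-KO": 0.05},                      # T-cell-like: old KO only
            "pop3": {"old-WT": 0.08, "old-KO": 0.08},      # monocyte-like: old, both
        })
    if preset == "fig6":
        return GeneratorSpec(**common, infiltration={
            # WAT-like signal: age-increased in both genotypes, blunted in KO
            "pop1": {"young-WT": 0.02, "young-KO": 0.02,
                     "old-WT": 0.15, "old-KO": 0.05},
        })
    raise ValidationError(f"unknown preset {preset!r} (expected null, fig5 or fig6)")


PRESET_POPULATION_ROLES = {
    "fig5": {"pop1": "B-like", "pop2": "T-like", "pop3": "monocyte-like"},
    "fig6": {"pop1": "WAT-like"},
}


def make_preset(preset: str, seed: int = 0):
    """Generate the full scenario: compendium + study sharing marker truth.

    Returns ``(compendium_matrix, compendium_design, study_matrix,
    study_design, truth)`` where ``truth`` merges compendium markers with the
    study's planted structure.
    """
    spec = preset_spec(preset, seed=seed)
    comp_matrix, comp_design, comp_truth = make_compendium(spec)
    study_matrix, study_design, truth = make_study(
        replace(spec, with_detection=True), marker_genes=comp_truth.marker_genes)
    return comp_matrix, comp_design, study_matrix, study_design, truth
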