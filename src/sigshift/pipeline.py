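"""End-to-end orchestration: the full study analysis and the qPCR analysis.

``run_study`` fits the four group contrasts and the genotype-by-age
interaction, derives compendium signatures, computes enrichment rankings and
comparison tables, and writes everything as TSV plus a JSON run manifest
(config snapshot, file digests, wall clock per stage) so a run is fully
inspectable and reproducible.

``run_qpcr`` performs the relative-expression (2^-ddCt) analysis with
protected-LSD letter displays per gene and tissue.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sigshift import __version__
from sigshift.data import Config, SampleTable, StageError, ValidationError
from sigshift.diffexpr import call_degs, fit_moderated, interaction_fit
from sigshift.enrichment import compare_rankings, rank_signatures
from sigshift.io import (
    enrichment_table,
    read_expression,
    read_gmt,
    write_expression,
    write_gmt,
    write_sample_table,
    write_table,
)
from sigshift.signatures import derive_all, signatures_to_collection
from sigshift.stats import delta_delta_ct, protected_lsd, rank_correlation
from sigshift.synthetic import CONTRASTS, make_preset

logger = logging.getLogger("sigshift")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, outputs, digests, timings."""

    config: dict
    seed: int
    version: str = __version__
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def record(self, name: str, path: Path) -> None:
        self.outputs[str(name)] = {"path": str(path), "sha256": _digest(path)}

    def verify(self) -> None:
        for name, rec in self.outputs.items():
            p = Path(rec["path"])
            if not p.exists():
                raise ValidationError(f"manifest output {name!r} missing: {p}")
            if _digest(p) != rec["sha256"]:
                raise ValidationError(f"manifest output {name!r} digest mismatch: {p}")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_study(out_dir, config: Config | None = None, seed: int = 0,
              preset: str | None = None, matrix=None, design=None,
              signatures=None, matrix_path=None, meta_path=None,
              signatures_path=None) -> RunManifest:
    """Run the full study analysis and write all report tables.

    Inputs come either from a simulate preset (``preset`` + ``seed``) or from
    user data (in-memory objects or file paths). Outputs: one DE table per
    contrast plus the interaction, a DEG-count table, a genome-wide
    fold-change rank-correlation table, per-contrast enrichment tables over
    the signature collection, the aging-bias comparison table
    (delta signed Log10P, KO vs WT aging), and ``manifest.json``.
    """
    config = config or Config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.__dict__.copy(), seed=seed)
    stage = "setup"
    try:
        if preset is not None:
            stage = "simulate"
            t0 = time.perf_counter()
            comp_matrix, comp_design, matrix, design, truth = make_preset(preset, seed=seed)
            write_expression(matrix, out / "study_matrix.tsv")
            write_sample_table(design, out / "study_meta.tsv")
            with open(out / "truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
            for name in ("study_matrix.tsv", "study_meta.tsv", "truth.json"):
                manifest.record(name, out / name)
            manifest.inputs["preset"] = preset
            manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)

            stage = "signatures"
            t0 = time.perf_counter()
            sigs, summary = derive_all(comp_matrix, comp_design, config=config)
            signatures = signatures_to_collection(sigs)
            write_gmt(signatures, out / "signatures.gmt")
            write_table(summary, out / "signature_summary.tsv")
            manifest.record("signatures.gmt", out / "signatures.gmt")
            manifest.record("signature_summary.tsv", out / "signature_summary.tsv")
            manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        else:
            stage = "load"
            if matrix is None:
                if matrix_path is None or meta_path is None:
                    raise ValidationError("need matrix+meta (objects or paths)")
                matrix, design = read_expression(matrix_path, meta_path)
                manifest.inputs["matrix"] = {"path": str(matrix_path),
                                             "sha256": _digest(Path(matrix_path))}
                manifest.inputs["meta"] = {"path": str(meta_path),
                                           "sha256": _digest(Path(meta_path))}
            if signatures is None:
                if signatures_path is None:
                    raise ValidationError("need a signature collection (object or GMT path)")
                signatures = read_gmt(signatures_path)
                manifest.inputs["signatures"] = {"path": str(signatures_path),
                                                 "sha256": _digest(Path(signatures_path))}

        stage = "differential-expression"
        t0 = time.perf_counter()
        de_results = {}
        deg_rows = []
        for label, (a, b) in CONTRASTS.items():
            de = fit_moderated(matrix, design, (a, b), config=config)
            de_results[label] = de
            up, down = call_degs(de, fdr=config.fdr, fc_up=config.fc_up,
                                 fc_down=config.fc_down)
            fname = f"de_{label.replace('/', '_vs_')}.tsv"
            write_table(de, out / fname)
            manifest.record(fname, out / fname)
            deg_rows.append({"contrast": label, "n_included": len(de.included),
                             "n_up": len(up), "n_down": len(down)})
        inter = interaction_fit(matrix, design, config=config)
        write_table(inter, out / "de_interaction.tsv")
        manifest.record("de_interaction.tsv", out / "de_interaction.tsv")
        n_inter_nominal = int((inter.included["p"] < 0.05).sum())
        deg_rows.append({"contrast": "genotypexage", "n_included": len(inter.included),
                         "n_up": n_inter_nominal, "n_down": 0})
        write_table(pd.DataFrame(deg_rows), out / "deg_counts.tsv")
        manifest.record("deg_counts.tsv", out / "deg_counts.tsv")
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)

        stage = "fc-correlation"
        t0 = time.perf_counter()
        pairs = [
            ("aging: WT vs KO", "old-WT/young-WT", "old-KO/young-KO"),
            ("genotype: young vs old", "young-KO/young-WT", "old-KO/old-WT"),
        ]
        corr_rows = []
        for label, ca, cb in pairs:
            fa, fb = de_results[ca].fc_vector(), de_results[cb].fc_vector()
            common = fa.log2fc.index.intersection(fb.log2fc.index)
            rs = rank_correlation(fa.log2fc[common], fb.log2fc[common])
            corr_rows.append({"comparison": label, "contrast_a": ca,
                              "contrast_b": cb, "n_genes": len(common), "r_s": rs})
        write_table(pd.DataFrame(corr_rows), out / "fc_correlations.tsv")
        manifest.record("fc_correlations.tsv", out / "fc_correlations.tsv")
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)

        stage = "enrichment"
        t0 = time.perf_counter()
        for label, de in de_results.items():
            fname = f"enrich_{label.replace('/', '_vs_')}.tsv"
            results = rank_signatures(de.fc_vector(), signatures)
            write_table(enrichment_table(results), out / fname)
            manifest.record(fname, out / fname)
        delta = compare_rankings(de_results["old-KO/young-KO"].fc_vector(),
                                 de_results["old-WT/young-WT"].fc_vector(),
                                 signatures)
        write_table(delta, out / "aging_bias_comparison.tsv")
        manifest.record("aging_bias_comparison.tsv", out / "aging_bias_comparison.tsv")
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
    except Exception as err:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.json")
        raise StageError(stage, str(err)) from err

    manifest.write(out / "manifest.json")
    manifest.verify()
    return manifest


def run_qpcr(ct_table: pd.DataFrame, design: SampleTable,
             endogenous: str = "Rn18s", calibrator_group: str = "young-WT",
             alpha: float = 0.05, lsd_scale: str = "dct") -> pd.DataFrame:
    """Relative qPCR expression with group letters, per gene (and tissue).

    ``ct_table`` is long-format with columns ``sample_id``, ``gene``, ``ct``
    and optionally ``tissue``. For each gene (within each tissue), Ct values
    are normalized to the endogenous control of the same sample (dCt), then to
    the mean dCt of the calibrator group (ddCt), giving relative expression
    2^-ddCt whose calibrator-group mean is 1 by construction. Group means,
    standard errors and protected-LSD compact letters are reported; the LSD
    ANOVA runs on the dCt scale by default (``lsd_scale='rel'`` switches to
    the relative-expression scale).
    """
    required = {"sample_id", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise ValidationError(f"ct_table needs columns {sorted(required)}")
    if lsd_scale not in ("dct", "rel"):
        raise ValidationError("lsd_scale must be 'dct' or 'rel'")
    df = ct_table.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if "tissue" not in df.columns:
        df["tissue"] = "all"
    groups = design.table["group"].astype(str)

    rows = []
    for (tissue, gene), sub in df.groupby(["tissue", "gene"], sort=True):
        if gene == endogenous:
            continue
        endo = df[(df["tissue"] == tissue) & (df["gene"] == endogenous)]
        endo_ct = endo.set_index("sample_id")["ct"]
        missing = set(sub["sample_id"]) - set(endo_ct.index)
        if missing:
            raise ValidationError(
                f"missing endogenous control {endogenous!r} for samples "
                f"{sorted(missing)} (tissue {tissue!r}, gene {gene!r})")
        sub = sub.set_index("sample_id")
        dct = sub["ct"].astype(float) - endo_ct.loc[sub.index].astype(float)
        grp = groups.loc[dct.index]
        cal = dct[grp == calibrator_group]
        if len(cal) == 0:
            raise ValidationError(f"calibrator group {calibrator_group!r} absent "
                                  f"for gene {gene!r}, tissue {tissue!r}")
        rel = delta_delta_ct(sub["ct"].astype(float).to_numpy(),
                             endo_ct.loc[sub.index].astype(float).to_numpy(),
                             float(cal.mean()))
        rel = pd.Series(rel, index=dct.index)
        # normalize to the calibrator group's average expression (its
        # arithmetic mean is exactly 1 under this convention)
        rel = rel / rel[grp == calibrator_group].mean()
        # LSD on the variance-stabilized dCt scale by default; note the sign
        # flip (lower dCt = higher expression) does not affect the letters
        lsd_values = dct if lsd_scale == "dct" else rel
        by_group = {g: lsd_values[grp == g].to_numpy()
                    for g in sorted(grp.unique())}
        letters = protected_lsd(by_group, alpha=alpha)
        for g in sorted(grp.unique()):
            vals = rel[grp == g]
            rows.append({
                "tissue": tissue, "gene": gene, "group": g, "n": len(vals),
                "relative_expression": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                "letters": letters.letters[g],
                "omnibus_f_p": letters.f_p,
            })
    return pd.DataFrame(rows)
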