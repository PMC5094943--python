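"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices and sample metadata are plain TSV; gene sets are GMT v1;
result tables round-trip through TSV at 12-decimal precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from sigshift.data import (
    Config,
    DEResult,
    EnrichmentResult,
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger("sigshift")

FLOAT_FMT = "%.12g"


def read_expression(path, meta_path=None):
    """Read a genes-x-samples TSV (first column gene ids, header sample ids).

    Returns an :class:`ExpressionMatrix`, or ``(ExpressionMatrix, SampleTable)``
    when a metadata sidecar path is given. Row and column order are preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric value {v!r} at row {df.index[i]!r} "
                        f"(line {i + 2}), column {col!r} (field {j + 2})"
                    ) from None
        raise
    matrix = ExpressionMatrix(values)
    if meta_path is None:
        return matrix
    meta = read_sample_table(meta_path)
    meta.validate_against(matrix)
    return matrix, meta


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: sample metadata must have a sample_id column")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, fields name, description, members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m != ""]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning(
                    "GMT set %r (line %d): collapsed %d duplicate members",
                    name, lineno, len(members) - len(deduped),
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def de_table(result: DEResult) -> pd.DataFrame:
    """DEResult as a writable frame: gene order preserved, documented columns."""
    out = result.table.reset_index(names="gene")
    return out[["gene", "mean_a", "mean_b", "log2fc", "fc", "t", "p", "fdr", "included"]]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as a frame sorted by signed Log10P descending."""
    rows = []
    for r in results:
        rows.append({
            "signature": r.signature,
            "n_used": r.n_used,
            "n_dropped": r.n_dropped,
            "mean_fc": r.mean_fc,
            "sig_fc_q25": r.sig_fc_quartiles[0],
            "sig_fc_q50": r.sig_fc_quartiles[1],
            "sig_fc_q75": r.sig_fc_quartiles[2],
            "bg_fc_q25": r.bg_fc_quartiles[0],
            "bg_fc_q50": r.bg_fc_quartiles[1],
            "bg_fc_q75": r.bg_fc_quartiles[2],
            "rank_sum_p": r.rank_sum_p,
            "signed_log10p": r.signed_log10p,
            "n_up": r.n_up,
            "n_down": r.n_down,
            "direction_p": r.direction_p,
            "null_band_lo": r.null_band[0],
            "null_band_hi": r.null_band[1],
            "auc": r.auc,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["signed_log10p", "signature"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def write_table(result, path) -> None:
    """Write a DEResult, a list of EnrichmentResults, or a DataFrame as TSV.

    Column and row order are deterministic; numeric values round-trip to 12
    significant digits.
    """
    if isinstance(result, DEResult):
        df = de_table(result)
    elif isinstance(result, list) and all(isinstance(r, EnrichmentResult) for r in result):
        df = enrichment_table(result)
    elif isinstance(result, pd.DataFrame):
        df = result
    else:
        raise ValidationError(f"cannot serialize {type(result).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fc_vector(path):
    """Read a DE table written by :func:`write_table` back as an FCVector."""
    from sigshift.data import FCVector

    df = read_table(path)
    if "included" in df.columns:
        df = df.loc[df["included"].astype(bool)]
    return FCVector(pd.Series(df["log2fc"].to_numpy(), index=df["gene"].astype(str)),
                    comparison=str(path))


def load_config(path=None, **overrides) -> Config:
    """Load thresholds from a flat-key YAML file, with keyword overrides."""
    params = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config must be a flat mapping")
        params.update(loaded)
    params.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(Config.__dataclass_fields__)
    unknown = set(params) - valid
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return Config(**params)


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the given level."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
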