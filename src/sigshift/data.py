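"""Domain containers: expression matrices, sample metadata, gene sets, results.

All expression values are log2-scale intensities. Linear fold changes are
always derived as ``2 ** (difference of log2 group means)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("sigshift")


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated at construction."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


class ExpressionMatrix:
    """Gene-by-sample matrix of log2 expression intensities.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns, or a
        2-D array together with ``gene_ids`` / ``sample_ids``.
    detection
        Optional boolean gene-by-sample matrix of above-background detection
        calls, same shape and labels as ``values``.
    """

    def __init__(self, values, gene_ids=None, sample_ids=None, detection=None):
        if isinstance(values, pd.DataFrame):
            df = values.copy()
            df.index = df.index.astype(str)
            df.columns = df.columns.astype(str)
        else:
            if gene_ids is None or sample_ids is None:
                raise ValidationError("gene_ids and sample_ids required for array input")
            df = pd.DataFrame(
                np.asarray(values, dtype=float),
                index=[str(g) for g in gene_ids],
                columns=[str(s) for s in sample_ids],
            )
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        self.values = df
        if detection is not None:
            det = pd.DataFrame(detection) if not isinstance(detection, pd.DataFrame) else detection.copy()
            if det.shape != df.shape:
                raise ValidationError(
                    f"detection shape {det.shape} != expression shape {df.shape}"
                )
            det.index = df.index
            det.columns = df.columns
            detection = det.astype(bool)
        self.detection = detection

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        det = self.detection[list(sample_ids)] if self.detection is not None else None
        return ExpressionMatrix(self.values[list(sample_ids)], detection=det)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


class SampleTable:
    """Per-sample metadata: group label, genotype/age factors, population label.

    For a 2x2 genotype-by-age study design, genotype takes values WT/KO and age
    young/old, and all four cells must be non-empty when the design is used.
    """

    COLUMNS = ("group", "genotype", "age", "population")

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        _check_unique(df.index, "sample")
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in_group(self, group: str, column: str = "group") -> list[str]:
        if column not in self.table.columns:
            raise ValidationError(f"sample table has no {column!r} column")
        mask = self.table[column].astype(str) == group
        return list(self.table.index[mask])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        extra = set(matrix.sample_ids) - set(self.sample_ids)
        if missing or extra:
            raise ValidationError(
                f"sample table / matrix mismatch; missing from matrix: {sorted(missing)}, "
                f"unannotated samples: {sorted(extra)}"
            )

    def validate_two_by_two(self) -> None:
        for col in ("genotype", "age"):
            if col not in self.table.columns:
                raise ValidationError(f"2x2 design requires a {col!r} column")
        counts = self.table.groupby(["genotype", "age"], observed=True).size()
        for gt in sorted(self.table["genotype"].unique()):
            for age in sorted(self.table["age"].unique()):
                if (gt, age) not in counts.index or counts[(gt, age)] == 0:
                    raise ValidationError(f"empty design cell: genotype={gt}, age={age}")

    def __repr__(self) -> str:
        return f"SampleTable({len(self.table)} samples, columns={list(self.table.columns)})"


class GeneSetCollection:
    """Named gene sets (signature sets, annotation categories)."""

    def __init__(self, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        for name, genes in sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} contains duplicate members")
        self.sets = {str(k): [str(g) for g in v] for k, v in sets.items()}
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


@dataclass
class Config:
    """Pipeline thresholds and derivation parameters.

    Defaults are the study conventions: differential expression at FDR < 0.10
    with linear FC > 1.50 or < 0.67 (strict inequalities); above-background
    detection at signed-rank p < 0.05 required in at least one third of the
    samples in a comparison; two-stage signature selection keeping the 150
    lowest-p fold-change-concordant genes, then the 100 most extreme by FC.
    """

    fdr: float = 0.10
    fc_up: float = 1.50
    fc_down: float = 0.67
    detect_alpha: float = 0.05
    min_detect_fraction: float = 1.0 / 3.0
    n_p: int = 150
    n_sig: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fdr < 1):
            raise ValidationError(f"fdr must be in (0,1), got {self.fdr}")
        if not self.fc_up > 1:
            raise ValidationError(f"fc_up must exceed 1, got {self.fc_up}")
        if not (0 < self.fc_down < 1):
            raise ValidationError(f"fc_down must be in (0,1), got {self.fc_down}")
        if not (0 < self.min_detect_fraction <= 1):
            raise ValidationError("min_detect_fraction must be in (0,1]")
        if self.n_sig > self.n_p:
            raise ValidationError(f"n_sig ({self.n_sig}) must be <= n_p ({self.n_p})")


class DEResult:
    """Per-gene differential expression result for one contrast.

    ``table`` columns: gene (index), mean_a, mean_b, log2fc, fc, t, p, fdr,
    included. Genes excluded by the detection filter are kept as rows with
    ``included == False`` and NaN statistics, never silently dropped.
    """

    COLUMNS = ["mean_a", "mean_b", "log2fc", "fc", "t", "p", "fdr", "included"]

    def __init__(self, table: pd.DataFrame, contrast: str, group_a: str = "a", group_b: str = "b"):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"DEResult table missing columns {missing}")
        inc = table["included"].astype(bool)
        sub = table.loc[inc]
        if len(sub):
            if not np.allclose(sub["fc"], 2.0 ** sub["log2fc"], rtol=1e-12, atol=0):
                raise ValidationError("fc != 2**log2fc")
            if np.any(sub["fdr"].to_numpy() < sub["p"].to_numpy() - 1e-12):
                raise ValidationError("BH-adjusted p below raw p")
        self.table = table
        self.contrast = contrast
        self.group_a = group_a
        self.group_b = group_b

    @property
    def included(self) -> pd.DataFrame:
        return self.table.loc[self.table["included"].astype(bool)]

    def fc_vector(self) -> "FCVector":
        sub = self.included
        return FCVector(pd.Series(sub["log2fc"].to_numpy(), index=sub.index), self.contrast)

    def __repr__(self) -> str:
        n = len(self.table)
        return f"DEResult({self.contrast!r}, {n} genes, {int(self.table['included'].sum())} included)"


class FCVector:
    """Per-gene log2 fold changes for one comparison (linear FC = 2**log2fc)."""

    def __init__(self, log2fc: pd.Series, comparison: str = ""):
        s = pd.Series(log2fc).astype(float)
        s.index = s.index.astype(str)
        _check_unique(s.index, "gene")
        if not np.all(np.isfinite(s.to_numpy())):
            raise ValidationError("non-finite log2 fold change")
        self.log2fc = s
        self.comparison = comparison

    @property
    def fc(self) -> pd.Series:
        return 2.0 ** self.log2fc

    def __len__(self) -> int:
        return len(self.log2fc)


@dataclass
class SignatureSet:
    """Genes selected as specifically expressed by one population.

    ``genes`` is ordered by derivation fold change (most extreme first);
    ``stats`` carries per-gene FC and p from the one-vs-rest contrast;
    ``direction`` is "up" (FC > 1 markers) or "down" (decreased-expression
    variant); ``truncated`` flags derivations where fewer than ``n_sig``
    candidates survived the fold-change concordance stage.
    """

    name: str
    genes: list[str]
    stats: pd.DataFrame
    direction: str = "up"
    n_p: int = 150
    n_sig: int = 100
    truncated: bool = False
    stage1_n: int = 0
    stage2_n: int = 0

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction must be up/down, got {self.direction!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")
        if len(self.genes) > self.n_sig:
            raise ValidationError(f"signature {self.name!r} exceeds n_sig={self.n_sig}")
        if len(self.genes):
            fcs = self.stats.loc[self.genes, "fc"].to_numpy()
            if self.direction == "up" and not np.all(fcs > 1):
                raise ValidationError(f"up-signature {self.name!r} contains FC <= 1 genes")
            if self.direction == "down" and not np.all(fcs < 1):
                raise ValidationError(f"down-signature {self.name!r} contains FC >= 1 genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Directional-bias summary for one signature against one FC vector."""

    signature: str
    n_used: int
    n_dropped: int
    mean_fc: float
    sig_fc_quartiles: tuple[float, float, float]
    bg_fc_quartiles: tuple[float, float, float]
    rank_sum_p: float
    signed_log10p: float
    n_up: int
    n_down: int
    bg_up: int
    bg_down: int
    direction_p: float = float("nan")
    null_band: tuple[int, int] = (0, 0)
    auc: float = float("nan")

    def __post_init__(self):
        if self.n_up + self.n_down != self.n_used:
            raise ValidationError("direction counts do not sum to n_used")
        if np.isfinite(self.auc) and not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"AUC out of [0,1]: {self.auc}")


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, for recovery testing."""

    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    interaction_genes: dict[str, float] = field(default_factory=dict)
    infiltration: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "marker_genes": self.marker_genes,
            "de_genes": self.de_genes,
            "interaction_genes": self.interaction_genes,
            "infiltration": self.infiltration,
        }
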