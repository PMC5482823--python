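"""Domain types, dataset loading/validation and shared analysis conventions.

The three tables every stage consumes:

* expression matrix — non-negative FPKM, genes in rows, samples in columns;
* gene annotation — gene_id, symbol, biotype, chromosome;
* sample metadata — sample_id, tissue, sex, individual.

All files are tab-delimited text with a header row (CSV accepted via the
``sep`` argument).  Fine-grained annotation biotypes are mapped onto four
coarse groups (protein_coding / ncRNA / pseudogene / other); unmapped labels
are hard errors rather than silently lumped into "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BIOTYPE_GROUPS",
    "BIOTYPE_MAP",
    "AnalysisConfig",
    "ExpressionMatrix",
    "GeneAnnotation",
    "SampleMetadata",
    "load_dataset",
    "validate_partition",
    "percent",
]

#: The four coarse biotype groups every annotation must partition into.
BIOTYPE_GROUPS = ("protein_coding", "ncRNA", "pseudogene", "other")

#: Mapping from fine annotation biotypes to the four coarse groups.  The
#: fine vocabulary follows Ensembl naming; anything absent here (and not
#: already one of the coarse labels) is rejected at load time.
BIOTYPE_MAP: dict[str, str] = {
    # coarse labels map to themselves
    "protein_coding": "protein_coding",
    "ncRNA": "ncRNA",
    "pseudogene": "pseudogene",
    "other": "other",
    # non-coding RNA
    "lncRNA": "ncRNA",
    "lincRNA": "ncRNA",
    "antisense": "ncRNA",
    "antisense_RNA": "ncRNA",
    "miRNA": "ncRNA",
    "snRNA": "ncRNA",
    "snoRNA": "ncRNA",
    "scaRNA": "ncRNA",
    "rRNA": "ncRNA",
    "tRNA": "ncRNA",
    "misc_RNA": "ncRNA",
    "sRNA": "ncRNA",
    "ribozyme": "ncRNA",
    "scRNA": "ncRNA",
    "vault_RNA": "ncRNA",
    "Mt_rRNA": "ncRNA",
    "Mt_tRNA": "ncRNA",
    "3prime_overlapping_ncRNA": "ncRNA",
    "bidirectional_promoter_lncRNA": "ncRNA",
    "macro_lncRNA": "ncRNA",
    "sense_intronic": "ncRNA",
    "sense_overlapping": "ncRNA",
    # pseudogenes
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "transcribed_unitary_pseudogene": "pseudogene",
    "translated_processed_pseudogene": "pseudogene",
    "translated_unprocessed_pseudogene": "pseudogene",
    "unitary_pseudogene": "pseudogene",
    "polymorphic_pseudogene": "pseudogene",
    "IG_pseudogene": "pseudogene",
    "IG_C_pseudogene": "pseudogene",
    "IG_V_pseudogene": "pseudogene",
    "IG_J_pseudogene": "pseudogene",
    "IG_D_pseudogene": "pseudogene",
    "TR_V_pseudogene": "pseudogene",
    "TR_J_pseudogene": "pseudogene",
    "rRNA_pseudogene": "pseudogene",
    "Mt_tRNA_pseudogene": "pseudogene",
    # everything else
    "processed_transcript": "other",
    "TEC": "other",
    "IG_C_gene": "other",
    "IG_D_gene": "other",
    "IG_J_gene": "other",
    "IG_LV_gene": "other",
    "IG_V_gene": "other",
    "TR_C_gene": "other",
    "TR_D_gene": "other",
    "TR_J_gene": "other",
    "TR_V_gene": "other",
    "retained_intron": "other",
    "non_stop_decay": "other",
    "nonsense_mediated_decay": "other",
}


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator rounded to ``decimals`` places.

    The single percentage convention used by every summary table.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative FPKM values, genes in rows, samples in columns.

    ``values`` is a pandas DataFrame indexed by gene_id with sample_id
    columns; row/column order is meaningful and preserved.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite FPKM at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        neg = arr < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise ValueError(
                f"negative FPKM {arr[g, s]} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.values.to_csv(path, sep=sep, index_label="gene_id")


@dataclass(frozen=True)
class GeneAnnotation:
    """gene_id -> symbol, coarse biotype, chromosome.

    ``table`` is indexed by gene_id with columns symbol, biotype,
    chromosome; biotype values are the four coarse groups.
    """

    table: pd.DataFrame

    REQUIRED = ("symbol", "biotype", "chromosome")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        unknown = set(self.table["biotype"]) - set(BIOTYPE_GROUPS)
        if unknown:
            raise ValueError(
                f"unknown biotype label(s) with no mapping: {sorted(unknown)}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def biotype_of(self, gene_id: str) -> str:
        return str(self.table.at[gene_id, "biotype"])

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index_label="gene_id")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GeneAnnotation":
        """Build from a table whose biotypes may be fine-grained labels."""
        tab = table.copy()
        mapped = []
        for gid, bt in zip(tab.index, tab["biotype"]):
            if bt not in BIOTYPE_MAP:
                raise ValueError(
                    f"unknown biotype label {bt!r} for gene {gid!r}; "
                    "no mapping onto the four coarse groups"
                )
            mapped.append(BIOTYPE_MAP[bt])
        tab["biotype"] = mapped
        return cls(tab)


@dataclass(frozen=True)
class SampleMetadata:
    """sample_id -> tissue, sex, individual (+ sexual-tissue flag).

    A tissue is "sexual" when all its samples come from one sex and the
    flag says so; the constructor enforces that a sexual tissue never mixes
    sexes.
    """

    table: pd.DataFrame

    REQUIRED = ("tissue", "sex", "individual")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        bad_sex = set(self.table["sex"]) - {"female", "male"}
        if bad_sex:
            raise ValueError(f"sex must be female/male, got: {sorted(bad_sex)}")
        if "sexual_tissue" not in self.table.columns:
            object.__setattr__(
                self, "table", self.table.assign(sexual_tissue=False)
            )
        for tissue, sub in self.table[self.table["sexual_tissue"]].groupby("tissue"):
            if sub["sex"].nunique() > 1:
                raise ValueError(
                    f"sexual tissue {tissue!r} appears in more than one sex"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.table["tissue"]:
            seen.setdefault(t, None)
        return list(seen)

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.table.index[self.table["tissue"] == tissue])

    def tissue_of(self, sample_id: str) -> str:
        return str(self.table.at[sample_id, "tissue"])

    def is_sexual(self, tissue: str) -> bool:
        sub = self.table[self.table["tissue"] == tissue]
        if sub.empty:
            raise KeyError(f"unknown tissue {tissue!r}")
        return bool(sub["sexual_tissue"].iloc[0])

    def nonsexual_tissues(self) -> list[str]:
        return [t for t in self.tissues if not self.is_sexual(t)]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)])

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index_label="sample_id")


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and conventions shared by all analysis stages.

    The expressed test uses >= (one consistent boundary convention);
    housekeeping/reference criteria use strict inequalities exactly as
    stated (> min FPKM, < max SD, < max deviation).
    """

    expressed_threshold: float = 0.1
    log_pseudocount: float = 1.0
    fc_pseudocount: float = 0.01
    deg_alpha: float = 0.05
    deg_fc: float = 2.0
    ts_fc_grid: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0, 32.0)
    ts_fc_default: float = 4.0
    sex_fc: float = 2.0
    hk_min_fpkm: float = 1.0
    hk_max_sd_log2: float = 1.0
    hk_max_dev_log2: float = 2.0
    ref_min_fpkm: float = 50.0
    ref_max_sd_log2: float = 0.5
    ref_max_dev_log2: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("rng_seed", "ts_fc_grid"):
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")
        if not all(f > 0 for f in self.ts_fc_grid):
            raise ValueError("ts_fc_grid thresholds must be > 0")
        if not (
            self.ref_min_fpkm >= self.hk_min_fpkm
            and self.ref_max_sd_log2 <= self.hk_max_sd_log2
            and self.ref_max_dev_log2 <= self.hk_max_dev_log2
        ):
            raise ValueError(
                "reference criteria must be at least as tight as housekeeping"
            )

    def with_overrides(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class LoadReport:
    """What the loader rejected, for the run manifest."""

    unannotated_genes: list[str] = field(default_factory=list)
    unmatched_samples: list[str] = field(default_factory=list)


def _read_table(path: str | Path, sep: str, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if index_col not in df.columns:
        raise ValueError(f"{path}: missing required column {index_col!r}")
    return df.set_index(index_col)


def load_dataset(
    matrix_path: str | Path,
    annotation_path: str | Path,
    metadata_path: str | Path,
    sep: str = "\t",
    strict: bool = True,
) -> tuple[ExpressionMatrix, GeneAnnotation, SampleMetadata, LoadReport]:
    """Load and cross-validate the matrix/annotation/metadata triple.

    With ``strict=True`` (default) any gene in the matrix without
    annotation, or sample-set mismatch between matrix and metadata, is a
    hard error; with ``strict=False`` unannotated genes are dropped and
    reported in the :class:`LoadReport`.
    """
    raw = pd.read_csv(matrix_path, sep=sep, dtype={0: str})
    first = raw.columns[0]
    raw = raw.set_index(first)
    raw.index.name = "gene_id"
    try:
        values = raw.astype(float)
    except ValueError as exc:
        # locate the offending cell for a useful message
        for gid, row in raw.iterrows():
            for sid, v in row.items():
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric FPKM {v!r} at gene {gid!r}, sample {sid!r}"
                    ) from exc
        raise
    matrix = ExpressionMatrix(values)

    annotation = GeneAnnotation.from_table(
        _read_table(annotation_path, sep, "gene_id")
    )
    meta_tab = _read_table(metadata_path, sep, "sample_id")
    if "sexual_tissue" in meta_tab.columns:
        meta_tab["sexual_tissue"] = meta_tab["sexual_tissue"].map(
            {"True": True, "False": False, "true": True, "false": False,
             "1": True, "0": False}
        )
        if meta_tab["sexual_tissue"].isna().any():
            raise ValueError("sexual_tissue column must be boolean-like")
    metadata = SampleMetadata(meta_tab)

    matrix_samples = set(matrix.sample_ids)
    meta_samples = set(metadata.sample_ids)
    if matrix_samples != meta_samples:
        diff = sorted(matrix_samples ^ meta_samples)
        raise ValueError(
            f"matrix/metadata sample mismatch; symmetric difference: {diff}"
        )
    # align metadata rows to matrix column order
    metadata = SampleMetadata(metadata.table.loc[matrix.sample_ids])

    unannotated = [g for g in matrix.gene_ids if g not in set(annotation.gene_ids)]
    report = LoadReport(unannotated_genes=unannotated)
    if unannotated:
        if strict:
            raise ValueError(
                f"{len(unannotated)} matrix gene(s) lack annotation, "
                f"e.g. {unannotated[:5]}"
            )
        matrix = ExpressionMatrix(matrix.values.drop(index=unannotated))
    return matrix, annotation, metadata, report


def validate_partition(annotation: GeneAnnotation) -> pd.Series:
    """Per-biotype gene counts over the four coarse groups.

    Counts always sum to the total number of annotated genes (groups absent
    from the annotation appear with count 0).
    """
    if annotation.table.empty:
        raise ValueError("annotation is empty")
    counts = annotation.table["biotype"].value_counts()
    out = pd.Series(
        {g: int(counts.get(g, 0)) for g in BIOTYPE_GROUPS}, name="n_genes"
    )
    assert int(out.sum()) == len(annotation.table)
    return out
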