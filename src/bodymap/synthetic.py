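"""Synthetic FPKM matrices with planted gene classes and spike-ins.

The generator produces datasets with the statistical structure the
analysis stages assume: lognormal FPKM, tissue-structured background
expression, planted housekeeping / reference / tissue-specific /
sex-dominated / silent genes with known effect sizes, and an optional
ERCC-style spike-in layer.  Every planted gene carries a ground-truth
label so recovery can be scored exactly.

Model (log2 scale): for gene g and sample s,

    log2 FPKM = mu_g + tau_{g, tissue(s)} + sigma_{g, sex(s)} + eps,
    eps ~ Normal(0, replicate_noise_sd_log2)

Silent genes are exact zeros, so the zero-row-removal rule has
unambiguous planted truth.  Identical (config, seed) gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from bodymap.core import ExpressionMatrix, GeneAnnotation, SampleMetadata

__all__ = [
    "DEFAULT_TISSUES",
    "SEXUAL_TISSUES",
    "SimulationConfig",
    "GroundTruth",
    "ERCCReference",
    "generate_dataset",
    "generate_ercc_reference",
    "spike_dataset",
    "generate_homology",
]

#: 13 non-sexual tissues plus 4 single-sex tissues.
DEFAULT_TISSUES = (
    "adrenal_gland",
    "brain",
    "forestomach",
    "heart",
    "kidney",
    "large_intestine",
    "liver",
    "lung",
    "muscle",
    "small_intestine",
    "spleen",
    "stomach",
    "thymus",
    "ovary",
    "uterus",
    "testis",
    "vesicular_gland",
)

#: tissue -> the single sex it occurs in.
SEXUAL_TISSUES: dict[str, str] = {
    "ovary": "female",
    "uterus": "female",
    "testis": "male",
    "vesicular_gland": "male",
}

#: tissues sampled with extra replicates by default.
_DEEP_TISSUES = ("brain", "liver", "kidney", "testis")

_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 20)) + ("chrX", "chrY")

_RATIO_GROUPS = {"4:1": 4.0, "1:1": 1.0, "2:3": 2.0 / 3.0, "1:2": 0.5}


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    sexual_tissues: Mapping[str, str] = field(
        default_factory=lambda: dict(SEXUAL_TISSUES)
    )
    samples_per_tissue: int | Mapping[str, int] | None = None  # None -> 4/2 rule
    biotype_proportions: tuple[float, float, float, float] = (0.51, 0.20, 0.18, 0.11)
    frac_silent: float = 0.25
    n_housekeeping: int = 100
    n_reference: int = 20
    hk_mean_log2_range: tuple[float, float] = (2.0, 7.0)
    ref_mean_log2_range: tuple[float, float] = (7.0, 9.0)
    hk_tissue_sd_log2: float = 0.2
    n_tissue_specific: int = 10  # per tissue
    ts_fold: float = 16.0
    n_sex_dominated: int = 4  # per non-sexual tissue, split between sexes
    sex_fold: float = 4.0
    baseline_log2_mean: float = 2.0
    baseline_log2_sd: float = 2.0
    background_tissue_sd_log2: float = 1.5
    replicate_noise_sd_log2: float = 0.25
    ercc_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_silent < 1:
            raise ValueError("frac_silent must be in [0, 1)")
        for name in (
            "hk_tissue_sd_log2",
            "baseline_log2_sd",
            "background_tissue_sd_log2",
            "replicate_noise_sd_log2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.planted_total() > self.n_genes:
            raise ValueError(
                f"gene budget over-committed: {self.planted_total()} planted "
                f"genes > n_genes = {self.n_genes}"
            )

    def n_silent(self) -> int:
        return int(round(self.frac_silent * self.n_genes))

    def n_nonsexual(self) -> int:
        return len([t for t in self.tissues if t not in self.sexual_tissues])

    def planted_total(self) -> int:
        return (
            self.n_housekeeping
            + self.n_reference
            + self.n_tissue_specific * len(self.tissues)
            + self.n_sex_dominated * self.n_nonsexual()
            + self.n_silent()
        )

    def samples_for(self, tissue: str) -> int:
        if self.samples_per_tissue is None:
            return 4 if tissue in _DEEP_TISSUES else 2
        if isinstance(self.samples_per_tissue, int):
            return self.samples_per_tissue
        return int(self.samples_per_tissue[tissue])


@dataclass(frozen=True)
class GroundTruth:
    """Planted class per gene.

    ``table`` is indexed by gene_id with columns:
    class (housekeeping / reference / tissue_specific / sex_dominated /
    silent / background), target_tissue, target_sex, effect_log2 (planted
    log2 effect size; 0 for non-planted classes).
    """

    table: pd.DataFrame

    CLASSES = (
        "housekeeping",
        "reference",
        "tissue_specific",
        "sex_dominated",
        "silent",
        "background",
    )

    def ids_of(self, cls: str, tissue: str | None = None) -> set[str]:
        sub = self.table[self.table["class"] == cls]
        if tissue is not None:
            sub = sub[sub["target_tissue"] == tissue]
        return set(sub.index)

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index_label="gene_id")


@dataclass(frozen=True)
class ERCCReference:
    """Spike-in id -> theoretical Mix 1 / Mix 2 concentrations (attomol/ul).

    92 spikes in four mix-ratio groups of 23; concentrations span at least
    2^18; each spike's mix1/mix2 ratio equals its group's nominal ratio
    exactly.
    """

    table: pd.DataFrame  # index spike_id; mix1, mix2, ratio_group

    def __post_init__(self) -> None:
        if (self.table[["mix1", "mix2"]] <= 0).any().any():
            raise ValueError("ERCC concentrations must be > 0")

    @property
    def spike_ids(self) -> list[str]:
        return list(self.table.index)

    def concentrations(self, mix: str) -> pd.Series:
        if mix not in ("Mix1", "Mix2"):
            raise ValueError(f"mix must be Mix1 or Mix2, got {mix!r}")
        return self.table["mix1" if mix == "Mix1" else "mix2"]

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index_label="spike_id")

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str = "\t") -> "ERCCReference":
        tab = pd.read_csv(path, sep=sep).set_index("spike_id")
        return cls(tab.astype({"mix1": float, "mix2": float}))


def _build_metadata(config: SimulationConfig) -> SampleMetadata:
    rows = []
    for tissue in config.tissues:
        n = config.samples_for(tissue)
        if tissue in config.sexual_tissues:
            sexes = [config.sexual_tissues[tissue]] * n
        else:
            # alternate sexes so each non-sexual tissue has both
            sexes = ["female" if i % 2 == 0 else "male" for i in range(n)]
        for i, sex in enumerate(sexes):
            rows.append(
                {
                    "sample_id": f"{tissue}_{sex[0].upper()}{i + 1}",
                    "tissue": tissue,
                    "sex": sex,
                    "individual": f"mouse{(i % 4) + 1}",
                    "sexual_tissue": tissue in config.sexual_tissues,
                }
            )
    tab = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(tab)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneAnnotation, SampleMetadata, GroundTruth]:
    """Simulate the full (matrix, annotation, metadata, truth) quadruple."""
    rng = np.random.default_rng(config.seed)
    meta = _build_metadata(config)
    samples = meta.sample_ids
    tissues = list(config.tissues)
    n_genes, n_samples = config.n_genes, len(samples)
    tissue_idx = {t: i for i, t in enumerate(tissues)}
    sample_tissue = np.array([tissue_idx[meta.tissue_of(s)] for s in samples])
    sample_female = np.array(
        [meta.table.at[s, "sex"] == "female" for s in samples]
    )

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]

    # assign classes to gene slots, planted classes first
    classes = np.full(n_genes, "background", dtype=object)
    target_tissue = np.full(n_genes, "", dtype=object)
    target_sex = np.full(n_genes, "", dtype=object)
    effect = np.zeros(n_genes)
    cursor = 0

    def take(k: int) -> slice:
        nonlocal cursor
        sl = slice(cursor, cursor + k)
        cursor += k
        return sl

    hk_sl = take(config.n_housekeeping)
    classes[hk_sl] = "housekeeping"
    ref_sl = take(config.n_reference)
    classes[ref_sl] = "reference"
    ts_slices: dict[str, slice] = {}
    for t in tissues:
        sl = take(config.n_tissue_specific)
        classes[sl] = "tissue_specific"
        target_tissue[sl] = t
        effect[sl] = np.log2(config.ts_fold)
        ts_slices[t] = sl
    sex_slices: dict[str, slice] = {}
    for t in tissues:
        if t in config.sexual_tissues:
            continue
        sl = take(config.n_sex_dominated)
        classes[sl] = "sex_dominated"
        target_tissue[sl] = t
        for j in range(sl.start, sl.stop):
            target_sex[j] = "female" if (j - sl.start) % 2 == 0 else "male"
        effect[sl] = np.log2(config.sex_fold)
        sex_slices[t] = sl
    silent_sl = take(config.n_silent())
    classes[silent_sl] = "silent"

    # gene-level baseline (log2)
    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    lo, hi = config.hk_mean_log2_range
    mu[hk_sl] = rng.uniform(lo, hi, config.n_housekeeping)
    rlo, rhi = config.ref_mean_log2_range
    mu[ref_sl] = rng.uniform(rlo, rhi, config.n_reference)

    # tissue effects.  Background genes get a graded spread (a permuted,
    # scaled ramp): cross-tissue SD is background_tissue_sd_log2-scale, so
    # they fail the stability criteria, while the gap between the top two
    # tissues stays small, so they do not masquerade as tissue-specific.
    n_t = len(tissues)
    ramp = np.linspace(-1.0, 1.0, n_t)
    ramp = ramp / ramp.std() if n_t > 1 else ramp
    scale = config.background_tissue_sd_log2 * rng.uniform(0.8, 1.2, n_genes)
    perms = np.argsort(rng.random((n_genes, n_t)), axis=1)
    tau = ramp[perms] * scale[:, None] + rng.normal(0.0, 0.1, (n_genes, n_t))
    tau[hk_sl, :] = rng.normal(
        0.0, config.hk_tissue_sd_log2, (config.n_housekeeping, len(tissues))
    )
    tau[ref_sl, :] = rng.normal(
        0.0, min(config.hk_tissue_sd_log2, 0.15), (config.n_reference, len(tissues))
    )
    for t, sl in ts_slices.items():
        tau[sl, :] = 0.0
        tau[sl, tissue_idx[t]] = np.log2(config.ts_fold)
    # sex-dominated genes keep background tissue structure: their planted
    # effect is the within-tissue sex fold, nothing about tissue flatness

    # per-sample expected log2 expression
    log2_expr = mu[:, None] + tau[:, sample_tissue]

    # sex effect: only within the target non-sexual tissue
    for t, sl in sex_slices.items():
        in_t = sample_tissue == tissue_idx[t]
        for j in range(sl.start, sl.stop):
            boosted = in_t & (sample_female == (target_sex[j] == "female"))
            log2_expr[j, boosted] += np.log2(config.sex_fold)

    noise = rng.normal(0.0, config.replicate_noise_sd_log2, (n_genes, n_samples))
    fpkm = np.exp2(log2_expr + noise)
    fpkm[silent_sl, :] = 0.0

    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    )

    # annotation: biotypes by configured proportions, chromosomes uniform
    props = np.asarray(config.biotype_proportions, dtype=float)
    props = props / props.sum()
    biotypes = rng.choice(
        ["protein_coding", "ncRNA", "pseudogene", "other"], size=n_genes, p=props
    )
    chroms = rng.choice(_CHROMOSOMES[:-1], size=n_genes)  # no chrY genes
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "symbol": [f"Sym{i:05d}" for i in range(n_genes)],
                "biotype": biotypes,
                "chromosome": chroms,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )

    truth = GroundTruth(
        pd.DataFrame(
            {
                "class": classes,
                "target_tissue": target_tissue,
                "target_sex": target_sex,
                "effect_log2": effect,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    return matrix, annotation, meta, truth


def generate_ercc_reference(seed: int = 0) -> ERCCReference:
    """92 synthetic spike-ins in four ratio groups of 23.

    Concentrations follow the real spike-in design shape (wide log-spaced
    dynamic range >= 2^18, four mix-ratio groups) but are generated, not
    copied from a vendor table.
    """
    rng = np.random.default_rng(seed)
    groups = list(_RATIO_GROUPS)
    rows = []
    k = 0
    for group in groups:
        ratio = _RATIO_GROUPS[group]
        # 23 log2-spaced concentrations spanning 2^19.8
        exponents = np.linspace(-3.0, 16.8, 23)
        exponents = rng.permutation(exponents)
        for e in exponents:
            mix1 = float(2.0**e)
            rows.append(
                {
                    "spike_id": f"ERCC-{k:05d}",
                    "mix1": mix1,
                    "mix2": mix1 / ratio,
                    "ratio_group": group,
                }
            )
            k += 1
    tab = pd.DataFrame(rows).set_index("spike_id")
    return ERCCReference(tab)


def spike_dataset(
    matrix: ExpressionMatrix,
    ref: ERCCReference,
    mix_assignment: Mapping[str, str],
    noise_sd_log2: float = 0.0,
    seed: int = 0,
    ercc_fraction: float = 0.01,
    overrides: Mapping[str, str | float] | None = None,
) -> ExpressionMatrix:
    """Append 92 spike-in rows, scaled to ``ercc_fraction`` of each total.

    ``overrides`` maps sample_id -> "missing" (all-zero spikes) or a float
    fraction (e.g. 0.0596 to mimic a degraded sample with inflated
    spike-in signal).
    """
    overrides = dict(overrides or {})
    existing = [g for g in matrix.gene_ids if g.startswith("ERCC-")]
    if existing:
        raise ValueError(f"matrix already contains spike rows, e.g. {existing[0]!r}")
    missing_assign = [s for s in matrix.sample_ids if s not in mix_assignment]
    if missing_assign:
        raise ValueError(f"samples without a mix assignment: {missing_assign}")

    rng = np.random.default_rng(seed)
    spike_ids = ref.spike_ids
    cols = {}
    for s in matrix.sample_ids:
        conc = ref.concentrations(mix_assignment[s]).to_numpy()
        noisy = conc * np.exp2(rng.normal(0.0, noise_sd_log2, len(conc)))
        override = overrides.get(s)
        if override == "missing":
            cols[s] = np.zeros(len(conc))
            continue
        frac = float(override) if override is not None else ercc_fraction
        total_bio = float(matrix.values[s].sum())
        target = frac / (1.0 - frac) * total_bio
        cols[s] = noisy * (target / noisy.sum())
    spikes = pd.DataFrame(cols, index=pd.Index(spike_ids, name="gene_id"))
    return ExpressionMatrix(pd.concat([matrix.values, spikes]))


def generate_homology(
    truth: GroundTruth,
    n_foreign_hk: int,
    overlap_fraction: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Synthetic cross-species homology map plus a foreign stable-gene list.

    Builds a one-to-one mapping from a subset of the simulated genes to
    foreign ids, and a foreign "housekeeping" list of ``n_foreign_hk``
    genes of which round(overlap_fraction * n_foreign_hk) map onto planted
    housekeeping/reference genes.

    Returns ``(mapping, foreign_hk_ids)`` where mapping has columns
    gene_id, foreign_id.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hk_ids = sorted(truth.ids_of("housekeeping") | truth.ids_of("reference"))
    other_ids = sorted(set(truth.table.index) - set(hk_ids))
    n_overlap = int(round(overlap_fraction * n_foreign_hk))
    if n_overlap > len(hk_ids):
        raise ValueError(
            f"need {n_overlap} planted stable genes for overlap, "
            f"only {len(hk_ids)} available"
        )
    if n_foreign_hk - n_overlap > len(other_ids):
        raise ValueError("n_foreign_hk exceeds mappable non-housekeeping genes")
    pick_hk = list(rng.choice(hk_ids, size=n_overlap, replace=False))
    pick_other = list(
        rng.choice(other_ids, size=n_foreign_hk - n_overlap, replace=False)
    )
    mapped_mouse = pick_hk + pick_other
    mapping = pd.DataFrame(
        {
            "gene_id": mapped_mouse,
            "foreign_id": [f"hsa{i:05d}" for i in range(len(mapped_mouse))],
        }
    )
    foreign_hk = set(mapping["foreign_id"])
    return mapping, foreign_hk
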