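"""Two-tier stable-gene selection: housekeeping and reference genes.

A gene is a housekeeping candidate when (i) its FPKM exceeds 1 in every
sample, (ii) the standard deviation of its per-tissue mean log2(FPKM) is
below 1, and (iii) no tissue's mean log2(FPKM) deviates from the
cross-tissue average by 2 or more (i.e. no fourfold deviation).  The
reference tier tightens the same three criteria to FPKM > 50, SD < 0.5
and deviation < 1 (twofold), so the reference set is nested inside the
housekeeping set.

Notes on conventions:

* Stability statistics use log2 WITHOUT pseudocount; criterion (i)
  guarantees positivity for candidates, and genes containing any zero
  automatically fail (i) instead of being rescued by a pseudocount.
* "Across tissues" means across per-tissue mean log2 values, not across
  raw samples (a per-sample mode is available).
* SD across tissues is the population SD (divide by n): the tissue panel
  is the whole frame of reference, not a sample from one.
* All three inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bodymap.core import AnalysisConfig, ExpressionMatrix, GeneAnnotation, SampleMetadata, percent

__all__ = [
    "StabilityStats",
    "HousekeepingResult",
    "stability_stats",
    "identify_housekeeping",
    "select_reference_genes",
    "gene_variability_report",
    "homology_overlap",
    "chromosome_distribution",
]


@dataclass(frozen=True)
class StabilityStats:
    """Per-gene expression-stability statistics.

    ``table`` columns: min_sample_fpkm, sd_across_tissues, max_abs_dev,
    max_fold_variability, available (False for genes containing a zero,
    whose log-scale stats are undefined).  ``tissue_means`` holds the
    per-tissue mean log2(FPKM) matrix for available genes.
    """

    table: pd.DataFrame
    tissue_means: pd.DataFrame

    def __post_init__(self) -> None:
        avail = self.table[self.table["available"]]
        assert (avail["sd_across_tissues"] >= 0).all()
        assert (avail["max_abs_dev"] >= 0).all()
        assert (avail["max_fold_variability"] >= 1 - 1e-12).all()


@dataclass(frozen=True)
class HousekeepingResult:
    """Selected gene set for one tier plus per-gene diagnostics.

    ``diagnostics`` columns: selected (bool) and fail_reason (first failed
    criterion, empty when selected).
    """

    tier: str  # "housekeeping" or "reference"
    genes: frozenset[str]
    diagnostics: pd.DataFrame
    min_fpkm: float
    max_sd_log2: float
    max_dev_log2: float


def stability_stats(
    matrix: ExpressionMatrix, meta: SampleMetadata, per_sample: bool = False
) -> StabilityStats:
    """Compute per-gene stability statistics over per-tissue log2 means.

    With ``per_sample=True`` every sample is its own group, i.e. the SD
    and deviation criteria are evaluated across samples instead of across
    tissue means.
    """
    tissues = meta.tissues
    vals = matrix.values
    min_fpkm = vals.min(axis=1)
    available = (vals > 0).all(axis=1)

    logv = pd.DataFrame(
        np.where(vals.to_numpy() > 0, np.log2(np.where(vals.to_numpy() > 0, vals.to_numpy(), 1.0)), np.nan),
        index=vals.index,
        columns=vals.columns,
    )
    if per_sample:
        tmeans = logv.copy()
    else:
        tmeans = pd.DataFrame(
            {t: logv[meta.samples_of(t)].mean(axis=1) for t in tissues}
        )
    overall = tmeans.mean(axis=1)
    sd = tmeans.std(axis=1, ddof=0)
    dev = (tmeans.sub(overall, axis=0)).abs().max(axis=1)
    fold_var = np.exp2(tmeans.max(axis=1) - tmeans.min(axis=1))

    table = pd.DataFrame(
        {
            "min_sample_fpkm": min_fpkm,
            "sd_across_tissues": sd.where(available),
            "max_abs_dev": dev.where(available),
            "max_fold_variability": fold_var.where(available),
            "available": available,
        },
        index=vals.index,
    )
    return StabilityStats(table, tmeans.where(available))


def _select(
    stats: StabilityStats,
    tier: str,
    min_fpkm: float,
    max_sd: float,
    max_dev: float,
) -> HousekeepingResult:
    t = stats.table
    fails_i = (~t["available"] | ~(t["min_sample_fpkm"] > min_fpkm)).to_numpy()
    fails_ii = (~(t["sd_across_tissues"] < max_sd)).to_numpy()
    fails_iii = (~(t["max_abs_dev"] < max_dev)).to_numpy()
    labels = (
        (fails_i, f"criterion (i): FPKM <= {min_fpkm} in some sample"),
        (fails_ii, f"criterion (ii): SD across tissues >= {max_sd}"),
        (fails_iii, f"criterion (iii): tissue deviation >= {max_dev}"),
    )
    reasons = np.array(
        [
            "; ".join(lab for mask, lab in labels if mask[i])
            for i in range(len(t))
        ],
        dtype=object,
    )
    selected = ~(fails_i | fails_ii | fails_iii)
    diag = pd.DataFrame(
        {"selected": selected, "fail_reason": reasons}, index=t.index
    )
    return HousekeepingResult(
        tier=tier,
        genes=frozenset(t.index[selected]),
        diagnostics=diag,
        min_fpkm=min_fpkm,
        max_sd_log2=max_sd,
        max_dev_log2=max_dev,
    )


def identify_housekeeping(
    stats: StabilityStats, config: AnalysisConfig | None = None
) -> HousekeepingResult:
    """Housekeeping tier: FPKM > 1, SD(log2) < 1, max deviation < 2."""
    cfg = config or AnalysisConfig()
    return _select(
        stats, "housekeeping", cfg.hk_min_fpkm, cfg.hk_max_sd_log2, cfg.hk_max_dev_log2
    )


def select_reference_genes(
    stats: StabilityStats, config: AnalysisConfig | None = None
) -> HousekeepingResult:
    """Reference tier: FPKM > 50, SD(log2) < 0.5, max deviation < 1."""
    cfg = config or AnalysisConfig()
    return _select(
        stats, "reference", cfg.ref_min_fpkm, cfg.ref_max_sd_log2, cfg.ref_max_dev_log2
    )


def gene_variability_report(
    stats: StabilityStats,
    gene_ids: list[str],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Fold-variability diagnostic for named genes (the classic
    Gapdh/Actb/B2m sanity check): max fold difference between the highest
    and lowest tissue plus pass/fail for both tiers."""
    missing = [g for g in gene_ids if g not in stats.table.index]
    if missing:
        raise KeyError(f"unknown gene id(s): {missing}")
    hk = identify_housekeeping(stats, config)
    ref = select_reference_genes(stats, config)
    sub = stats.table.loc[gene_ids]
    return pd.DataFrame(
        {
            "max_fold_variability": sub["max_fold_variability"],
            "housekeeping": [g in hk.genes for g in gene_ids],
            "hk_fail_reason": hk.diagnostics.loc[gene_ids, "fail_reason"],
            "reference": [g in ref.genes for g in gene_ids],
        },
        index=sub.index,
    )


def homology_overlap(
    set_a: set[str],
    set_b: set[str],
    mapping: pd.DataFrame,
) -> dict:
    """Overlap between an own-namespace gene set and a foreign set.

    ``mapping`` has columns gene_id (own namespace) and foreign_id.  The
    foreign set is translated through the mapping; percentages are
    reported both ways at 1-decimal precision:

    * pct_of_foreign = 100 * overlap / |foreign genes with a homolog|
    * pct_of_own     = 100 * overlap / |set_a|
    """
    for col in ("gene_id", "foreign_id"):
        if col not in mapping.columns:
            raise ValueError(f"mapping missing column {col!r}")
    fwd = mapping.set_index("foreign_id")["gene_id"]
    mapped_b = {fwd[f] for f in set_b if f in fwd.index}
    overlap = set_a & mapped_b
    return {
        "n_own": len(set_a),
        "n_foreign": len(set_b),
        "n_foreign_mapped": len(mapped_b),
        "n_overlap": len(overlap),
        "pct_of_foreign": percent(len(overlap), len(mapped_b)) if mapped_b else 0.0,
        "pct_of_own": percent(len(overlap), len(set_a)) if set_a else 0.0,
        "overlap_ids": sorted(overlap),
    }


def chromosome_distribution(
    gene_set: set[str], annotation: GeneAnnotation
) -> pd.DataFrame:
    """Per-chromosome count of the set and fraction of that chromosome's
    annotated genes."""
    unknown = gene_set - set(annotation.gene_ids)
    if unknown:
        raise ValueError(f"gene(s) missing annotation: {sorted(unknown)[:5]}")
    chrom = annotation.table["chromosome"]
    totals = chrom.value_counts()
    in_set = chrom.loc[sorted(gene_set)].value_counts()
    out = pd.DataFrame(
        {
            "n_in_set": in_set.reindex(totals.index, fill_value=0),
            "n_on_chromosome": totals,
        }
    )
    out["fraction_of_chromosome"] = out["n_in_set"] / out["n_on_chromosome"]
    assert int(out["n_in_set"].sum()) == len(gene_set)
    return out.sort_index()
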