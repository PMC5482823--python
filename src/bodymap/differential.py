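"""Pairwise tissue DEG calling, tissue-specific and sex-dominated genes.

DEG calling: per-gene two-sided Welch t-test on log2(FPKM+1) values,
Benjamini-Hochberg adjustment within each tissue pair, and a fold-change
filter on linear-scale tissue means with a small pseudocount
(default 0.01, separate from the log transform's 1).  A gene is called
when q < alpha and the fold change is >= fc or <= 1/fc.

Tissue-specific calling: a gene is specific to tissue t at fold
threshold f when its (pseudocounted) mean in t is more than f-fold above
its mean in every other tissue.  Calls are nested across the threshold
grid by construction.

Sex-dominated calling is fold-only (mean ratio > fc within one
non-sexual tissue); the number of replicates per sex is typically too
small for a useful test, though one can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bodymap.core import ExpressionMatrix, SampleMetadata
from bodymap.landscape import LogMatrix

__all__ = [
    "DEGTable",
    "TissueSpecificCalls",
    "SexDominatedCalls",
    "benjamini_hochberg",
    "pairwise_deg",
    "deg_count_matrix",
    "tissue_specific",
    "sex_dominated",
]


@dataclass(frozen=True)
class DEGTable:
    """Per-gene differential result for one tissue pair (A vs B)."""

    tissue_a: str
    tissue_b: str
    table: pd.DataFrame  # mean_a, mean_b, log2fc, p_value, q_value, call
    alpha: float
    fc: float

    @property
    def up_in_a(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up_in_A"])

    @property
    def down_in_a(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down_in_A"])


@dataclass(frozen=True)
class TissueSpecificCalls:
    """Best candidate tissue and achieved min-fold per gene, plus the
    call set at each threshold of the fold-change grid."""

    table: pd.DataFrame  # best_tissue, achieved_fc, call_at_<f> columns
    fc_grid: tuple[float, ...]

    def calls_at(self, fc: float) -> dict[str, str]:
        """gene_id -> specific tissue for calls at threshold ``fc``."""
        col = _fc_col(fc)
        if col not in self.table.columns:
            raise KeyError(f"threshold {fc} not in grid {self.fc_grid}")
        sub = self.table[self.table[col]]
        return {str(g): str(t) for g, t in sub["best_tissue"].items()}

    def count_per_tissue(self, fc: float) -> pd.Series:
        calls = self.calls_at(fc)
        return pd.Series(calls).value_counts().rename("n_tissue_specific")


@dataclass(frozen=True)
class SexDominatedCalls:
    """Fold-based sex comparison for one non-sexual tissue."""

    tissue: str
    fc: float
    table: pd.DataFrame  # mean_female, mean_male, fold_f_over_m, call

    @property
    def female_dominated(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "female_dominated"])

    @property
    def male_dominated(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "male_dominated"])


def _fc_col(fc: float) -> str:
    return f"call_at_{fc:g}"


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest p downwards enforces monotonicity
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t per row; degenerate rows handled explicitly.

    Zero variance in both groups: p = 1 when the means agree (no signal),
    p = 0 when they differ (infinite evidence at face value).
    """
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    same = degenerate & (a.mean(axis=1) == b.mean(axis=1))
    p[degenerate] = 0.0
    p[same] = 1.0
    return p


def pairwise_deg(
    logm: LogMatrix,
    meta: SampleMetadata,
    tissue_a: str,
    tissue_b: str,
    alpha: float = 0.05,
    fc: float = 2.0,
    fc_pseudocount: float = 0.01,
    equal_var: bool = False,
) -> DEGTable:
    """Welch t-test + per-pair BH + linear fold filter for one tissue pair."""
    samples_a = [s for s in meta.samples_of(tissue_a) if s in set(logm.sample_ids)]
    samples_b = [s for s in meta.samples_of(tissue_b) if s in set(logm.sample_ids)]
    for t, ss in ((tissue_a, samples_a), (tissue_b, samples_b)):
        if len(ss) < 2:
            raise ValueError(f"tissue {t!r} has {len(ss)} sample(s); need >= 2")
    log_a = logm.values[samples_a].to_numpy()
    log_b = logm.values[samples_b].to_numpy()

    if equal_var:
        p = np.asarray(
            stats.ttest_ind(log_a, log_b, axis=1, equal_var=True).pvalue, dtype=float
        )
        degenerate = (log_a.var(axis=1, ddof=1) == 0) & (
            log_b.var(axis=1, ddof=1) == 0
        )
        same = degenerate & (log_a.mean(axis=1) == log_b.mean(axis=1))
        p[degenerate] = 0.0
        p[same] = 1.0
    else:
        p = _welch_pvalues(log_a, log_b)
    q = benjamini_hochberg(p)

    fpkm = logm.to_fpkm()
    mean_a = fpkm[samples_a].mean(axis=1).clip(lower=0.0)
    mean_b = fpkm[samples_b].mean(axis=1).clip(lower=0.0)
    ratio = (mean_a + fc_pseudocount) / (mean_b + fc_pseudocount)
    log2fc = np.log2(ratio)

    call = np.full(len(p), "none", dtype=object)
    sig = (q < alpha) & (np.abs(log2fc) >= np.log2(fc))
    call[sig & (log2fc.to_numpy() > 0)] = "up_in_A"
    call[sig & (log2fc.to_numpy() < 0)] = "down_in_A"

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "call": call,
        },
        index=logm.values.index,
    )
    return DEGTable(tissue_a, tissue_b, table, alpha, fc)


def deg_count_matrix(
    logm: LogMatrix,
    meta: SampleMetadata,
    alpha: float = 0.05,
    fc: float = 2.0,
    fc_pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Tissue x tissue up-regulated DEG counts.

    Entry (A, B) counts genes up in A versus B, so the matrix is
    antisymmetric in the up/down sense: up(A,B) == down(B,A).
    """
    tissues = meta.tissues
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    counts = pd.DataFrame(0, index=tissues, columns=tissues, dtype=int)
    for i, a in enumerate(tissues):
        for b in tissues[i + 1 :]:
            deg = pairwise_deg(logm, meta, a, b, alpha, fc, fc_pseudocount)
            counts.loc[a, b] = len(deg.up_in_a)
            counts.loc[b, a] = len(deg.down_in_a)
    return counts


def tissue_specific(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    fc_grid: Sequence[float] = (2.0, 4.0, 8.0, 16.0, 32.0),
    fc_pseudocount: float = 0.01,
    expressed_threshold: float = 0.1,
) -> TissueSpecificCalls:
    """Min-fold-over-all-other-tissues specificity calls across a grid.

    For each gene the candidate tissue is the one maximising
    achieved_fc = min over other tissues o of
    (mean_t + pc) / (mean_o + pc); a call at threshold f additionally
    requires achieved_fc > f and mean_t >= expressed_threshold.
    """
    tissues = meta.tissues
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    grid = tuple(sorted(float(f) for f in fc_grid))
    means = pd.DataFrame(
        {t: matrix.values[meta.samples_of(t)].mean(axis=1) for t in tissues}
    )
    shifted = means.to_numpy() + fc_pseudocount
    n_t = len(tissues)
    # achieved fold for each candidate tissue: mean_t / max over others
    max_other = np.empty_like(shifted)
    for j in range(n_t):
        others = np.delete(shifted, j, axis=1)
        max_other[:, j] = others.max(axis=1)
    fold = shifted / max_other
    best_j = fold.argmax(axis=1)
    rows_idx = np.arange(shifted.shape[0])
    achieved = fold[rows_idx, best_j]
    best_tissue = np.array(tissues, dtype=object)[best_j]
    best_mean = means.to_numpy()[rows_idx, best_j]

    table = pd.DataFrame(
        {"best_tissue": best_tissue, "achieved_fc": achieved,
         "best_tissue_mean": best_mean},
        index=matrix.values.index,
    )
    eligible = best_mean >= expressed_threshold
    for f in grid:
        table[_fc_col(f)] = (achieved > f) & eligible
    return TissueSpecificCalls(table, grid)


def sex_dominated(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    tissue: str,
    fc: float = 2.0,
    fc_pseudocount: float = 0.01,
    with_test: bool = False,
    alpha: float = 0.05,
) -> SexDominatedCalls:
    """Female/male fold comparison within one non-sexual tissue."""
    if meta.is_sexual(tissue):
        raise ValueError(f"{tissue!r} is a sexual tissue; sexes not comparable")
    sub = meta.table[meta.table["tissue"] == tissue]
    f_samples = list(sub.index[sub["sex"] == "female"])
    m_samples = list(sub.index[sub["sex"] == "male"])
    if not f_samples or not m_samples:
        raise ValueError(f"tissue {tissue!r} lacks samples of one sex")
    mean_f = matrix.values[f_samples].mean(axis=1)
    mean_m = matrix.values[m_samples].mean(axis=1)
    fold = (mean_f + fc_pseudocount) / (mean_m + fc_pseudocount)
    call = np.full(len(fold), "none", dtype=object)
    call[fold.to_numpy() > fc] = "female_dominated"
    call[fold.to_numpy() < 1.0 / fc] = "male_dominated"
    if with_test:
        if len(f_samples) < 2 or len(m_samples) < 2:
            raise ValueError("with_test requires >= 2 samples per sex")
        log_f = np.log2(matrix.values[f_samples] + 1.0).to_numpy()
        log_m = np.log2(matrix.values[m_samples] + 1.0).to_numpy()
        p = _welch_pvalues(log_f, log_m)
        call[benjamini_hochberg(p) >= alpha] = "none"
    table = pd.DataFrame(
        {
            "mean_female": mean_f,
            "mean_male": mean_m,
            "fold_f_over_m": fold,
            "call": call,
        },
        index=matrix.values.index,
    )
    return SexDominatedCalls(tissue, fc, table)
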