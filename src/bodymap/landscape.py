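"""Expression landscape: expressed/ubiquitous flags, summaries, clustering.

Conventions: a gene is *expressed* in a sample when FPKM >= threshold
(default 0.1; the >= boundary is applied consistently everywhere), and
*ubiquitously expressed* when it meets the threshold in every sample.
Before log transformation, all-zero rows are removed and a pseudocount of
1 is added (log2(FPKM + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from bodymap.core import (
    BIOTYPE_GROUPS,
    ExpressionMatrix,
    GeneAnnotation,
    SampleMetadata,
    percent,
)

__all__ = [
    "ExpressionFlags",
    "LogMatrix",
    "ClusterReport",
    "flag_expressed",
    "biotype_summary",
    "expressed_per_tissue",
    "make_log_matrix",
    "cluster_samples",
    "flag_outliers",
    "pca_summary",
]


@dataclass(frozen=True)
class ExpressionFlags:
    """Per-gene expressed / ubiquitous flags.

    table columns: expressed (bool), n_samples_expressed (int),
    ubiquitous (bool); indexed by gene_id.
    """

    table: pd.DataFrame
    n_samples: int
    threshold: float

    def __post_init__(self) -> None:
        t = self.table
        assert (t["n_samples_expressed"].between(0, self.n_samples)).all()
        assert (t["expressed"] == (t["n_samples_expressed"] >= 1)).all()
        assert not (t["ubiquitous"] & ~t["expressed"]).any()

    @property
    def expressed_ids(self) -> set[str]:
        return set(self.table.index[self.table["expressed"]])

    @property
    def ubiquitous_ids(self) -> set[str]:
        return set(self.table.index[self.table["ubiquitous"]])


@dataclass(frozen=True)
class LogMatrix:
    """log2(FPKM + pseudocount) matrix with all-zero rows removed."""

    values: pd.DataFrame
    removed_genes: tuple[str, ...]
    pseudocount: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def to_fpkm(self) -> pd.DataFrame:
        """Invert the transform (up to float rounding)."""
        return np.exp2(self.values) - self.pseudocount


@dataclass(frozen=True)
class ClusterReport:
    """Pairwise sample distances, merge tree, and per-sample outlier flags."""

    distance: pd.DataFrame  # symmetric, zero diagonal
    linkage: np.ndarray  # scipy linkage matrix
    metric: str
    method: str

    def __post_init__(self) -> None:
        d = self.distance.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def nearest_neighbor(self, sample_id: str) -> tuple[str, float]:
        row = self.distance.loc[sample_id].drop(sample_id)
        nn = row.idxmin()
        return str(nn), float(row[nn])

    def merge_table(self) -> pd.DataFrame:
        n = self.distance.shape[0]
        lk = self.linkage
        return pd.DataFrame(
            {
                "node": np.arange(n, n + lk.shape[0]),
                "left": lk[:, 0].astype(int),
                "right": lk[:, 1].astype(int),
                "height": lk[:, 2],
                "size": lk[:, 3].astype(int),
            }
        )


def flag_expressed(matrix: ExpressionMatrix, threshold: float = 0.1) -> ExpressionFlags:
    """Expressed (>= threshold in >= 1 sample) / ubiquitous (all samples)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    hits = matrix.values.to_numpy() >= threshold
    n_expr = hits.sum(axis=1)
    table = pd.DataFrame(
        {
            "expressed": n_expr >= 1,
            "n_samples_expressed": n_expr,
            "ubiquitous": n_expr == matrix.n_samples,
        },
        index=matrix.values.index,
    )
    return ExpressionFlags(table, n_samples=matrix.n_samples, threshold=threshold)


def biotype_summary(flags: ExpressionFlags, annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-biotype expressed / silent counts and 1-decimal percentages."""
    unannotated = set(flags.table.index) - set(annotation.gene_ids)
    if unannotated:
        raise ValueError(
            f"flagged gene(s) lack annotation, e.g. {sorted(unannotated)[:5]}"
        )
    bt = annotation.table.loc[flags.table.index, "biotype"]
    rows = []
    for group in BIOTYPE_GROUPS:
        sub = flags.table[bt == group]
        total = len(sub)
        if total == 0:
            continue
        n_expr = int(sub["expressed"].sum())
        rows.append(
            {
                "biotype": group,
                "total": total,
                "expressed": n_expr,
                "silent": total - n_expr,
                "pct_expressed": percent(n_expr, total),
            }
        )
    return pd.DataFrame(rows).set_index("biotype")


def expressed_per_tissue(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    threshold: float = 0.1,
    mode: str = "mean",
) -> pd.Series:
    """Expressed-gene count per tissue.

    ``mode='mean'`` (default) averages per-sample counts within each
    tissue; ``mode='union'`` counts genes expressed in any sample of the
    tissue.
    """
    if mode not in ("mean", "union"):
        raise ValueError(f"mode must be 'mean' or 'union', got {mode!r}")
    out = {}
    for tissue in meta.tissues:
        samples = meta.samples_of(tissue)
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no samples")
        hits = matrix.values[samples].to_numpy() >= threshold
        if mode == "mean":
            out[tissue] = float(hits.sum(axis=0).mean())
        else:
            out[tissue] = int(hits.any(axis=1).sum())
    return pd.Series(out, name=f"n_expressed_{mode}")


def make_log_matrix(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> LogMatrix:
    """Drop all-zero rows, then log2(FPKM + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    vals = matrix.values
    zero_rows = (vals == 0).all(axis=1)
    removed = tuple(vals.index[zero_rows])
    kept = vals.loc[~zero_rows]
    return LogMatrix(np.log2(kept + pseudocount), removed, pseudocount)


def _pairwise_distance(values: pd.DataFrame, metric: str) -> pd.DataFrame:
    samples = values.columns
    arr = values.to_numpy()
    if metric in ("pearson", "spearman"):
        if metric == "spearman":
            arr = pd.DataFrame(arr).rank(axis=0).to_numpy()
        sd = arr.std(axis=0)
        flat = [str(samples[i]) for i in np.where(sd == 0)[0]]
        if flat:
            raise ValueError(
                f"zero-variance sample(s), correlation undefined: {flat}"
            )
        d = 1.0 - np.corrcoef(arr, rowvar=False)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
    elif metric == "euclidean":
        sq = (arr[:, :, None] - arr[:, None, :]) ** 2
        d = np.sqrt(sq.sum(axis=0))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=samples, columns=samples)


def cluster_samples(
    logm: LogMatrix, metric: str = "pearson", method: str = "average"
) -> ClusterReport:
    """Agglomerative sample clustering on 1 - correlation distance.

    Default reproduces the conventional transcriptome-QC recipe: pairwise
    1 - Pearson r over log2(FPKM+1) genes, average linkage.  Merge heights
    are non-decreasing for the supported linkages on this metric.
    """
    if logm.values.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    dist = _pairwise_distance(logm.values, metric)
    lk = hierarchy.linkage(squareform(dist.to_numpy(), checks=False), method=method)
    return ClusterReport(distance=dist, linkage=lk, metric=metric, method=method)


def flag_outliers(report: ClusterReport, meta: SampleMetadata) -> pd.DataFrame:
    """Flag samples whose nearest neighbor comes from a different tissue.

    A sample is only eligible when its own tissue has >= 2 samples
    (a singleton tissue has no same-tissue neighbor to expect).  Returns a
    table of flagged samples with tissue, offending neighbor and reason.
    """
    tissue_counts = meta.table["tissue"].value_counts()
    rows = []
    for s in report.distance.index:
        tissue = meta.tissue_of(s)
        if tissue_counts[tissue] < 2:
            continue
        nn, d = report.nearest_neighbor(s)
        nn_tissue = meta.tissue_of(nn)
        if nn_tissue != tissue:
            rows.append(
                {
                    "sample_id": s,
                    "tissue": tissue,
                    "nearest_neighbor": nn,
                    "neighbor_tissue": nn_tissue,
                    "distance": d,
                    "reason": (
                        f"nearest neighbor {nn} is {nn_tissue}, "
                        f"expected {tissue}"
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "tissue",
            "nearest_neighbor",
            "neighbor_tissue",
            "distance",
            "reason",
        ],
    ).set_index("sample_id")


def pca_summary(logm: LogMatrix, n_components: int = 2) -> dict:
    # thin convenience wrapper; not part of any acceptance-grade output
    centered = logm.values.to_numpy().T
    centered = centered - centered.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / max(centered.shape[0] - 1, 1)
    k = min(n_components, len(s))
    return {
        "scores": pd.DataFrame(
            u[:, :k] * s[:k],
            index=logm.sample_ids,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        "explained_variance_ratio": var[:k] / var.sum(),
    }
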