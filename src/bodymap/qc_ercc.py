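"""Spike-in QC: per-sample linearity and spike-fraction anomaly flags.

Each sample's detected spike-ins (measured FPKM > 0) are regressed in
log-log space against the theoretical concentration of the mix assigned
to that sample; R^2 is the squared Pearson correlation of the two log
vectors.  The spike fraction is the spike FPKM sum over the total FPKM
sum.  Flags, in precedence order:

    missing_spike_in  — fewer than ``min_detected`` spikes detected, or
                        spike fraction below ``min_fraction``
    excess_spike_in   — spike fraction above ``max_fraction``
    poor_linearity    — R^2 below ``min_r2``
    ok                — otherwise

The anomaly bounds act on FPKM fractions, a stand-in for read-count
fractions: nominal spike-in input is about 1% of mRNA content, so the
default band is 0.1% - 3%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from bodymap.core import ExpressionMatrix
from bodymap.synthetic import ERCCReference

__all__ = ["ERCCQCReport", "ercc_qc", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS: dict[str, float] = {
    "min_r2": 0.8,
    "min_fraction": 0.001,
    "max_fraction": 0.03,
    "min_detected": 8,
}


@dataclass(frozen=True)
class ERCCQCReport:
    """Per-sample spike-in QC table.

    columns: r_squared, slope, n_detected, spike_fraction, flag.
    """

    table: pd.DataFrame
    thresholds: dict

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flag"] != "ok"]


def _loglog_fit(measured: np.ndarray, conc: np.ndarray, pseudocount: float):
    x = np.log2(conc)
    y = np.log2(measured + pseudocount)
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope)


def ercc_qc(
    matrix: ExpressionMatrix,
    ref: ERCCReference,
    mix_assignment: Mapping[str, str],
    thresholds: Mapping[str, float] | None = None,
    pseudocount: float = 0.01,
    spike_prefix: str = "ERCC-",
) -> ERCCQCReport:
    """Per-sample spike-in linearity and fraction QC."""
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    spike_ids = [g for g in matrix.gene_ids if g.startswith(spike_prefix)]
    if not spike_ids:
        raise ValueError(
            f"matrix contains no spike rows (prefix {spike_prefix!r})"
        )
    unassigned = [s for s in matrix.sample_ids if s not in mix_assignment]
    if unassigned:
        raise ValueError(f"samples without a mix assignment: {unassigned}")

    spikes = matrix.values.loc[spike_ids]
    rows = []
    for s in matrix.sample_ids:
        conc = ref.table.loc[spike_ids, :]
        conc_vals = (
            conc["mix1"] if mix_assignment[s] == "Mix1" else conc["mix2"]
        ).to_numpy()
        measured = spikes[s].to_numpy()
        detected = measured > 0
        n_det = int(detected.sum())
        total = float(matrix.values[s].sum())
        frac = float(measured.sum() / total) if total > 0 else 0.0
        r2, slope = _loglog_fit(
            measured[detected], conc_vals[detected], pseudocount
        )
        if n_det < th["min_detected"] or frac < th["min_fraction"]:
            flag = "missing_spike_in"
        elif frac > th["max_fraction"]:
            flag = "excess_spike_in"
        elif not np.isnan(r2) and r2 < th["min_r2"]:
            flag = "poor_linearity"
        else:
            flag = "ok"
        rows.append(
            {
                "sample_id": s,
                "r_squared": r2,
                "slope": slope,
                "n_detected": n_det,
                "spike_fraction": frac,
                "flag": flag,
            }
        )
    table = pd.DataFrame(rows).set_index("sample_id")
    return ERCCQCReport(table, th)
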