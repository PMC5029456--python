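"""miRNA expression: RPMM normalization, expression filter, and
estrogen-responsiveness by fold change versus time zero.

Small-RNA counts are placed on a reads-per-million-mapped (RPMM) scale per
library, miRNAs with a mean of >= 50 RPMM across all samples are kept, and
a miRNA is called responsive at level theta when some time point shows a
fold change >= theta (or <= 1/theta) versus the mean of the time-zero
replicates with an uncorrected Welch t-test p <= 0.05 — deliberately
without multiple-testing correction, matching the screening convention for
small candidate panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def rpmm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each library to reads per million mapped: count/total * 1e6."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    return counts / totals * 1e6


def filter_expressed(rpmm: pd.DataFrame, min_mean: float = 50.0) -> list:
    """miRNAs whose grand mean RPMM across all samples is >= ``min_mean``."""
    means = rpmm.mean(axis=1)
    return list(means.index[means >= min_mean])


def fold_change_vs_t0(rpmm: pd.DataFrame, metadata: pd.DataFrame,
                      pseudocount: float = 1.0) -> pd.DataFrame:
    """Fold-change matrix (miRNA x time point, t > 0): mean RPMM at t over
    the mean of the time-zero replicates, with a pseudocount guarding zero
    baselines."""
    meta = metadata.loc[rpmm.columns]
    s0 = meta.index[meta["time_h"] == 0.0]
    if len(s0) == 0:
        raise ValueError("no time-zero replicates present")
    base = rpmm[s0].mean(axis=1)
    out = {}
    for t in sorted(meta["time_h"].unique()):
        if t == 0.0:
            continue
        st = meta.index[meta["time_h"] == t]
        out[t] = (rpmm[st].mean(axis=1) + pseudocount) / (base + pseudocount)
    return pd.DataFrame(out)


@dataclass
class MiRNAResponse:
    """Per-miRNA response calls and the underlying per-timepoint table."""

    table: pd.DataFrame          # mirna, time_h, fc, p
    expressed: list
    responsive: dict             # threshold -> list of miRNA ids

    @property
    def responsive_1p5(self):
        return self.responsive[1.5]

    @property
    def responsive_2(self):
        return self.responsive[2.0]

    def to_tsv(self, path) -> None:
        t = self.table.copy()
        t["expressed"] = t["mirna"].isin(self.expressed)
        for thr, ids in sorted(self.responsive.items()):
            t[f"responsive_{str(thr).replace('.', 'p')}"] = t["mirna"].isin(ids)
        t.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _welch_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def test_response(rpmm: pd.DataFrame, metadata: pd.DataFrame,
                  thresholds: tuple = (1.5, 2.0), alpha: float = 0.05,
                  min_mean: float = 50.0, pseudocount: float = 1.0,
                  equal_var: bool = False) -> MiRNAResponse:
    """Call responsive miRNAs.

    For each expressed miRNA and each time point t > 0, the per-replicate
    RPMM values at t are compared with those at time zero by a two-sample
    t-test (Welch by default; set ``equal_var`` for the pooled-variance
    variant).  Responsive at threshold theta iff some t has fc >= theta or
    fc <= 1/theta with p <= alpha.  Response calls are nested:
    responsive at 2.0 implies responsive at 1.5 implies expressed.
    """
    meta = metadata.loc[rpmm.columns]
    s0 = meta.index[meta["time_h"] == 0.0]
    if len(s0) < 2:
        raise ValueError("need >= 2 replicates at time zero")
    expressed = filter_expressed(rpmm, min_mean)
    fc = fold_change_vs_t0(rpmm, meta, pseudocount)
    rows = []
    for t in fc.columns:
        st = meta.index[meta["time_h"] == t]
        if len(st) < 2:
            raise ValueError(f"need >= 2 replicates at time {t}")
        x0 = rpmm[s0].to_numpy()
        xt = rpmm[st].to_numpy()
        for i, m in enumerate(rpmm.index):
            rows.append({
                "mirna": m, "time_h": t, "fc": fc.loc[m, t],
                "p": _welch_p(xt[i], x0[i], equal_var),
            })
    table = pd.DataFrame(rows)
    responsive = {}
    for thr in sorted(thresholds):
        hit = (
            ((table["fc"] >= thr) | (table["fc"] <= 1.0 / thr))
            & (table["p"] <= alpha)
        )
        ids = set(table.loc[hit, "mirna"]) & set(expressed)
        responsive[float(thr)] = [m for m in rpmm.index if m in ids]
    return MiRNAResponse(table=table, expressed=expressed, responsive=responsive)
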