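"""Normalization and per-timepoint differential expression for mRNA counts.

The analysis contract mirrors the standard count-based workflow: library
size factors by the median-of-ratios method, a negative-binomial Wald test
of each time point against time zero using a method-of-moments dispersion,
Benjamini-Hochberg adjustment within each timepoint contrast, and the
estrogen-responsiveness filters (mean normalized expression >= 500 across
the series; a significant, adjusted p < 0.05, >= twofold change versus time
zero at >= 1 time point), followed by the census of how many time points
each responsive gene crosses the twofold line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For every gene with strictly positive counts in all samples, the ratio
    of each sample's count to the gene's geometric mean is formed; a
    sample's factor is the median of those ratios.  Requires at least one
    all-positive gene.
    """
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; prefilter the "
            "count matrix before computing size factors"
        )
    xp = x[allpos]
    log_gm = np.log(xp).mean(axis=1, keepdims=True)
    ratios = xp / np.exp(log_gm)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    f = factors.reindex(counts.columns)
    if (f <= 0).any() or f.isna().any():
        raise ValueError("size factors must be positive and cover all samples")
    return counts / f


def estimate_dispersion(normalized: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-gene NB dispersion by method of moments.

    alpha_g = max(floor, (pooled within-group variance - mean) / mean^2),
    where the pooled variance weights each group's unbiased variance by its
    degrees of freedom and the mean is the grand mean of normalized counts.
    """
    g = groups.reindex(normalized.columns)
    if g.isna().any():
        raise ValueError("every sample needs a group label")
    num = np.zeros(len(normalized))
    df_total = 0
    for _, cols in normalized.T.groupby(g.to_numpy()):
        n_i = cols.shape[0]
        if n_i < 2:
            raise ValueError("every group needs >= 2 replicates")
        num += cols.var(axis=0, ddof=1).to_numpy() * (n_i - 1)
        df_total += n_i - 1
    pooled_var = num / df_total
    mean = normalized.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=normalized.index, name="dispersion")


def test_vs_t0(counts: pd.DataFrame, factors: pd.Series,
               dispersions: pd.Series, metadata: pd.DataFrame, t: float,
               pseudocount: float = 0.5):
    """NB Wald test of time ``t`` versus time zero for every gene.

    Returns (log2fc, p_raw) Series.  The fold change is
    log2((mean_t + c) / (mean_0 + c)) on normalized counts; the Wald
    statistic compares log group means with variance (1/m + alpha)/n per
    group (delta method on the NB mean-variance relation Var = m + alpha
    m^2), referenced against a t distribution with the design's pooled
    within-group degrees of freedom — the information the dispersion
    estimate rests on; a plain normal reference is visibly anticonservative
    at 3 replicates.  All-zero genes return (0, 1) by contract.
    """
    norm = normalize(counts, factors)
    s0 = metadata.index[metadata["time_h"] == 0.0]
    st = metadata.index[metadata["time_h"] == t]
    if len(s0) < 2 or len(st) < 2:
        raise ValueError(f"need >= 2 replicates at time 0 and time {t}")
    df = int(sum(n - 1 for n in metadata["time_h"].value_counts()))
    m0 = norm[s0].mean(axis=1).to_numpy()
    mt = norm[st].mean(axis=1).to_numpy()
    alpha = dispersions.reindex(norm.index).to_numpy()

    c = pseudocount
    log2fc = np.log2((mt + c) / (m0 + c))
    # variance of log mean, guarded at the pseudocount scale for empty groups
    m0g = np.maximum(m0, c)
    mtg = np.maximum(mt, c)
    var_log = (1.0 / m0g + alpha) / len(s0) + (1.0 / mtg + alpha) / len(st)
    z = (np.log(mtg) - np.log(m0g)) / np.sqrt(var_log)
    p = 2.0 * stats.t.sf(np.abs(z), df)
    dead = (m0 == 0) & (mt == 0)
    log2fc[dead] = 0.0
    p[dead] = 1.0
    return (pd.Series(log2fc, index=norm.index, name="log2fc"),
            pd.Series(p, index=norm.index, name="p_raw"))


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of one contrast's p-values."""
    p = np.asarray(p_raw, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene, per-timepoint differential expression versus time zero."""

    table: pd.DataFrame           # columns gene, time_h, log2fc, p_raw, p_adj
    mean_norm_expr: pd.Series     # per-gene mean normalized count, all samples
    size_factors: pd.Series
    dispersions: pd.Series

    def timepoints(self):
        return sorted(self.table["time_h"].unique())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_de(counts: pd.DataFrame, metadata: pd.DataFrame,
           pseudocount: float = 0.5) -> DEResult:
    """Full DE pass: size factors, MoM dispersions, one Wald contrast per
    non-zero time point, BH adjustment within each contrast."""
    meta = metadata.loc[counts.columns]
    factors = size_factors(counts)
    norm = normalize(counts, factors)
    disp = estimate_dispersion(norm, meta["time_h"])
    rows = []
    for t in sorted(meta["time_h"].unique()):
        if t == 0.0:
            continue
        lfc, p = test_vs_t0(counts, factors, disp, meta, t, pseudocount)
        rows.append(pd.DataFrame({
            "gene": counts.index, "time_h": t, "log2fc": lfc.to_numpy(),
            "p_raw": p.to_numpy(), "p_adj": adjust_bh(p.to_numpy()),
        }))
    table = pd.concat(rows, ignore_index=True)
    return DEResult(table=table, mean_norm_expr=norm.mean(axis=1),
                    size_factors=factors, dispersions=disp)


@dataclass
class ResponsiveGeneSet:
    """Genes passing the estrogen-responsiveness filters."""

    genes: list
    n_timepoints_2fold: pd.Series   # per responsive gene
    min_mean: float
    min_abs_log2fc: float
    alpha: float

    def to_frame(self, classes: dict | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "gene": self.genes,
            "class": [classes.get(g, "") if classes else "" for g in self.genes],
            "n_timepoints_2fold": self.n_timepoints_2fold.reindex(self.genes),
        })
        return df


def _significant_2fold(de: DEResult, min_abs_log2fc: float, alpha: float):
    t = de.table
    hit = (t["p_adj"] < alpha) & (t["log2fc"].abs() >= min_abs_log2fc)
    return t.assign(hit=hit).groupby("gene")["hit"].sum()


def select_responsive_genes(de: DEResult, min_mean: float = 500.0,
                            min_abs_log2fc: float = 1.0,
                            alpha: float = 0.05) -> ResponsiveGeneSet:
    """A gene is responsive iff its mean normalized expression across all
    samples is >= ``min_mean`` AND it shows a significant (adjusted
    p < alpha) change of |log2fc| >= ``min_abs_log2fc`` at >= 1 time point."""
    n_hits = _significant_2fold(de, min_abs_log2fc, alpha)
    mean_ok = de.mean_norm_expr >= min_mean
    members = [g for g in de.mean_norm_expr.index
               if mean_ok.get(g, False) and n_hits.get(g, 0) >= 1]
    return ResponsiveGeneSet(
        genes=members,
        n_timepoints_2fold=n_hits.reindex(members).astype(int),
        min_mean=min_mean, min_abs_log2fc=min_abs_log2fc, alpha=alpha,
    )


def census_timepoints(de: DEResult, responsive: ResponsiveGeneSet,
                      classes: dict | None = None):
    """Count, per responsive gene, how many time points reach a significant
    >= twofold change, plus the histogram over counts (and the per-class
    breakdown when class labels are supplied)."""
    if not responsive.genes:
        raise ValueError("responsive gene set is empty")
    n = responsive.n_timepoints_2fold
    n_timepoints = len(de.timepoints())
    hist = n.value_counts().reindex(range(1, n_timepoints + 1), fill_value=0)
    hist.index.name = "n_timepoints"
    breakdown = None
    if classes is not None:
        lab = pd.Series({g: classes.get(g, "unknown") for g in responsive.genes})
        breakdown = (
            pd.DataFrame({"n": n, "class": lab})
            .groupby(["class", "n"]).size().unstack(fill_value=0)
        )
    return n, hist, breakdown
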