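"""Temporal clustering of responsive-gene trajectories.

Each gene's log2 fold-change trajectory versus time zero is standardized to
unit maximum absolute value, interpolated onto an hourly grid with a
shape-preserving piecewise cubic Hermite polynomial (PCHIP), decomposed with
a Daubechies-3 discrete wavelet transform (periodized, orthonormal), and the
concatenated coefficient vectors are hierarchically clustered (Ward) and cut
into three clusters.  Clusters are then given semantic labels — transient,
induced, repressed — from the shape of their centroids on a linear
fold-change scale, and drop-then-recover (GATA3-like) versus mirror-image
profiles are pulled out by correlation with a template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.cluster import hierarchy
from scipy.interpolate import PchipInterpolator

DEFAULT_GRID = np.arange(0.0, 25.0)   # hourly, 25 points over 0..24 h


def interpolate_profile(times, values, grid=None) -> np.ndarray:
    """Shape-preserving monotone cubic interpolation onto ``grid``.

    The interpolant passes exactly through the observed values and does not
    overshoot local extremes between knots (the PCHIP property).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two observed time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.isnan(values).any() or np.isnan(times).any():
        raise ValueError("NaN in profile")
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.min() < times.min() or grid.max() > times.max():
        raise ValueError("grid must lie within the observed time range")
    return PchipInterpolator(times, values)(grid)


def wavelet_features(series, wavelet: str = "db3",
                     mode: str = "periodization") -> np.ndarray:
    """Full-depth discrete wavelet decomposition, coefficients concatenated
    coarsest-first.  The default periodized orthonormal transform preserves
    signal energy and admits perfect reconstruction."""
    series = np.asarray(series, dtype=float)
    w = pywt.Wavelet(wavelet)
    if series.size < w.dec_len:
        raise ValueError(
            f"series of length {series.size} is shorter than the {wavelet} "
            f"filter support ({w.dec_len})"
        )
    level = pywt.dwt_max_level(series.size, w.dec_len)
    coeffs = pywt.wavedec(series, w, mode=mode, level=level)
    return np.concatenate(coeffs)


def profile_matrix(log2fc: pd.DataFrame, times, grid=None,
                   standardize: bool = True):
    """Per-gene interpolated trajectories and wavelet feature vectors.

    ``log2fc`` is genes x observed time points (including time zero, where
    the fold change is 0 by construction).  Each row is scaled to unit
    max-abs (unless ``standardize`` is off), PCHIP-interpolated onto the
    grid, and wavelet-decomposed.  Returns (grid_profiles, features), both
    DataFrames indexed by gene.
    """
    if grid is None:
        grid = DEFAULT_GRID
    vals = log2fc.to_numpy(dtype=float)
    if standardize:
        scale = np.abs(vals).max(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        vals = vals / scale
    profiles = np.vstack([interpolate_profile(times, row, grid) for row in vals])
    feats = np.vstack([wavelet_features(p) for p in profiles])
    return (pd.DataFrame(profiles, index=log2fc.index, columns=grid),
            pd.DataFrame(feats, index=log2fc.index))


@dataclass
class ClusterAssignment:
    labels: pd.Series            # gene -> cluster index in {0, 1, 2}
    semantic: dict               # cluster index -> class label
    centroids: pd.DataFrame      # cluster index x grid, linear fold scale
    linkage_matrix: np.ndarray

    def classes(self) -> pd.Series:
        """gene -> semantic class label."""
        return self.labels.map(self.semantic)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.labels.index, "cluster": self.labels.to_numpy(),
            "label": self.classes().to_numpy(),
        })


def cluster_profiles(features: pd.DataFrame, k: int = 3,
                     method: str = "ward", metric: str = "euclidean"):
    """Agglomerative hierarchy on wavelet features, cut to exactly k
    clusters.  Returns (labels Series with clusters renumbered in first-seen
    order, linkage matrix)."""
    if len(features) < k:
        raise ValueError(f"need at least k={k} genes, got {len(features)}")
    Z = hierarchy.linkage(features.to_numpy(), method=method, metric=metric)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # renumber deterministically by order of first appearance
    remap: dict = {}
    labels = np.empty(len(raw), dtype=int)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap)
        labels[i] = remap[c]
    return pd.Series(labels, index=features.index, name="cluster"), Z


def label_classes(labels: pd.Series, fold_profiles: pd.DataFrame,
                  delta: float = 0.1):
    """Assign semantic labels to the k=3 clusters from centroid shape.

    Centroids are means of member profiles on a linear fold-change scale
    (time zero = 1).  With b = centroid(0), f = centroid(end), m = max:
    repressed iff f < b(1-delta); transient iff m > max(b, f)(1+delta) and
    not repressed; induced otherwise.  If the heuristic does not produce
    one label of each kind, labels are assigned by ranking: lowest f/b ->
    repressed, highest pulse excess m - max(b, f) -> transient, remainder
    -> induced.
    """
    clusters = sorted(labels.unique())
    if len(clusters) != 3:
        raise ValueError("label_classes expects exactly 3 clusters")
    cents = fold_profiles.groupby(labels).mean()
    semantic: dict = {}
    for c in clusters:
        cent = cents.loc[c].to_numpy()
        b, f, m = cent[0], cent[-1], cent.max()
        if f < b * (1.0 - delta):
            semantic[c] = "repressed"
        elif m > max(b, f) * (1.0 + delta):
            semantic[c] = "transient"
        else:
            semantic[c] = "induced"
    if sorted(semantic.values()) != ["induced", "repressed", "transient"]:
        stats = {c: (cents.loc[c].iloc[-1] / cents.loc[c].iloc[0],
                     cents.loc[c].max() - max(cents.loc[c].iloc[0],
                                              cents.loc[c].iloc[-1]))
                 for c in clusters}
        semantic = {}
        rep = min(clusters, key=lambda c: stats[c][0])
        semantic[rep] = "repressed"
        rest = [c for c in clusters if c != rep]
        tra = max(rest, key=lambda c: stats[c][1])
        semantic[tra] = "transient"
        semantic[[c for c in rest if c != tra][0]] = "induced"
    return semantic, cents


def cluster_trajectories(log2fc: pd.DataFrame, times, k: int = 3,
                         grid=None, method: str = "ward",
                         metric: str = "euclidean",
                         delta: float = 0.1) -> ClusterAssignment:
    """End-to-end: standardize, interpolate, wavelet-decompose, cluster, and
    label.  Semantic labeling uses centroids of the *linear fold-change*
    profiles (2**log2fc interpolated on the grid, unstandardized)."""
    grid_profiles, feats = profile_matrix(log2fc, times, grid)
    labels, Z = cluster_profiles(feats, k=k, method=method, metric=metric)
    fold = pd.DataFrame(
        np.vstack([
            interpolate_profile(times, row, grid if grid is not None else None)
            for row in 2.0 ** log2fc.to_numpy(dtype=float)
        ]),
        index=log2fc.index,
        columns=grid_profiles.columns,
    )
    semantic, cents = label_classes(labels, fold, delta)
    return ClusterAssignment(labels=labels, semantic=semantic,
                             centroids=cents, linkage_matrix=Z)


def default_recovery_template(grid=None, drop: float = 0.6,
                              recovery: float = 1.0 / 3.0) -> np.ndarray:
    """Canonical drop-then-partially-recover profile on the grid, linear
    fold scale (used when no data-derived template is supplied)."""
    if grid is None:
        grid = DEFAULT_GRID
    t = np.asarray(grid, dtype=float)
    return (1.0 - drop * (1.0 - np.exp(-t / 0.5))
            + drop * recovery * (1.0 - np.exp(-t / 6.0)))


def opposite_profile_groups(fold_profiles: pd.DataFrame, template=None,
                            r_threshold: float = 0.7):
    """Split drop-then-recover (GATA3-like) profiles from their mirror
    images by Pearson correlation with a template.

    ``fold_profiles`` holds grid trajectories (linear fold scale) of genes
    in the repressed and transient classes.  Genes with r >= threshold are
    template-like, r <= -threshold are opposite; zero-variance profiles are
    excluded with a warning.  When no template is given, the repressed-class
    members are subclustered into two and the subcentroid with the larger
    late-to-minimum recovery ratio is used.
    """
    X = fold_profiles.to_numpy(dtype=float)
    if template is None:
        feats = np.vstack([wavelet_features(row) for row in X])
        if len(X) >= 4:
            Z = hierarchy.linkage(feats, method="ward")
            sub = hierarchy.fcluster(Z, t=2, criterion="maxclust")
            cents = [X[sub == c].mean(axis=0) for c in (1, 2)]
            # keep only falling subcentroids, pick the one that recovers most
            falling = [c for c in cents if c[-1] < c[0]]
            pool = falling if falling else cents
            template = max(pool, key=lambda c: c[-1] / max(c.min(), 1e-12))
        else:
            template = default_recovery_template(fold_profiles.columns)
    template = np.asarray(template, dtype=float)
    tc = template - template.mean()
    tnorm = np.linalg.norm(tc)
    if tnorm == 0:
        raise ValueError("template profile has zero variance")
    like, anti = [], []
    for g, row in zip(fold_profiles.index, X):
        rc = row - row.mean()
        denom = np.linalg.norm(rc) * tnorm
        if denom == 0:
            warnings.warn(f"gene {g} has a zero-variance profile; skipped")
            continue
        r = float(rc @ tc / denom)
        if r >= r_threshold:
            like.append(g)
        elif r <= -r_threshold:
            anti.append(g)
    return like, anti


def dendrogram_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick string with merge
    heights as branch lengths."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
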