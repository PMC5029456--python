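"""miRNA family grouping, seed-site scanning, and Monte-Carlo target-site
enrichment for master-regulator ranking.

miRNAs sharing mature-sequence nucleotides 2-8 (the extended seed) form one
targeting family.  Canonical 3'-UTR site classes are scanned: the 8mer
(reverse complement of nt 2-8 followed by A), the 7mer-m8 (reverse
complement of nt 2-8), and the 7mer-1A (reverse complement of nt 2-7
followed by A); an 8mer occurrence is reported once, never additionally as
its constituent 7mers.  A family's target score on a gene set (number of
set genes with >= 1 site, or total site count) is compared with scores of
random gene sets of identical size drawn from the expressed-gene
background, giving an add-one empirical p-value
p = (1 + #{null >= observed}) / (1 + N); families are ranked by the sum of
-log10 p across all consecutive-timepoint gene sets.

Conservation weighting and network-hub scoring used by some master-
regulator pipelines are intentionally not part of this implementation; the
decision structure — site presence against a permutation null, summed over
intervals — is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import family_site_patterns, rna_to_dna

RNA_ALPHABET = set("ACGU")


@dataclass
class MiRNAFamily:
    family_id: str
    seed: str                    # nt 2-8, RNA alphabet
    members: list
    mean_rpmm: float = float("nan")


@dataclass
class TargetSiteHit:
    gene: str
    family_id: str
    site_type: str               # 8mer | 7mer-m8 | 7mer-1A
    start: int                   # 0-based on the UTR, 5'->3'


@dataclass
class EnrichmentResult:
    family_id: str
    set_id: str
    observed: float
    n_perm: int
    n_ge: int
    pvalue: float
    neg_log10_p: float


def group_families(mirna_table: pd.DataFrame, rpmm: pd.DataFrame | None = None,
                   min_mean: float = 50.0, agg: str = "max") -> list:
    """Group miRNAs into families by extended seed (mature nt 2-8).

    Family expression is the ``agg`` (max or sum) of member mean RPMM; when
    an RPMM matrix is supplied, families below ``min_mean`` are dropped.
    """
    member_means = rpmm.mean(axis=1) if rpmm is not None else None
    fams: dict = {}
    for _, row in mirna_table.iterrows():
        seq = str(row["mature_sequence"]).upper()
        if len(seq) < 8:
            raise ValueError(f"mature sequence of {row['mirna_id']} shorter than 8 nt")
        if not set(seq) <= RNA_ALPHABET:
            raise ValueError(
                f"non-RNA characters in mature sequence of {row['mirna_id']}"
            )
        seed = seq[1:8]
        fam = fams.setdefault(seed, {"ids": set(), "members": []})
        if "family_id" in row and isinstance(row.get("family_id"), str):
            fam["ids"].add(row["family_id"])
        fam["members"].append(row["mirna_id"])
    out = []
    for seed, fam in sorted(fams.items()):
        fid = fam["ids"].pop() if len(fam["ids"]) == 1 else f"fam-{seed}"
        if member_means is not None:
            vals = [member_means.get(m, 0.0) for m in fam["members"]]
            expr = max(vals) if agg == "max" else sum(vals)
            if expr < min_mean:
                continue
        else:
            expr = float("nan")
        out.append(MiRNAFamily(family_id=fid, seed=seed,
                               members=sorted(fam["members"]), mean_rpmm=expr))
    return out


def seed_sites(utr: str, family: MiRNAFamily, gene: str = "") -> list:
    """All canonical seed-site hits of ``family`` on a UTR (DNA, 5'->3').

    Overlapping distinct sites are all reported; an 8mer suppresses the
    7mer-m8 at the same start and the 7mer-1A at start + 1.
    """
    s = rna_to_dna(str(utr))
    pats = family_site_patterns(family.seed)
    rc7, p8, p1a = pats["7mer-m8"], pats["8mer"], pats["7mer-1A"]
    hits = []
    n = len(s)
    i = s.find(p8)
    while i >= 0:
        hits.append(TargetSiteHit(gene, family.family_id, "8mer", i))
        i = s.find(p8, i + 1)
    i = s.find(rc7)
    while i >= 0:
        if not (i + 7 < n and s[i + 7] == "A"):
            hits.append(TargetSiteHit(gene, family.family_id, "7mer-m8", i))
        i = s.find(rc7, i + 1)
    i = s.find(p1a)
    while i >= 0:
        if not (i >= 1 and s[i - 1] == rc7[0]):
            hits.append(TargetSiteHit(gene, family.family_id, "7mer-1A", i))
        i = s.find(p1a, i + 1)
    hits.sort(key=lambda h: (h.start, h.site_type))
    return hits


def site_counts(family: MiRNAFamily, utr_index: dict) -> pd.Series:
    """Per-gene number of seed sites of one family over a UTR collection."""
    return pd.Series({g: len(seed_sites(u, family, g))
                      for g, u in utr_index.items()}, name=family.family_id)


def target_score(genes, family: MiRNAFamily, utr_index: dict,
                 mode: str = "binary") -> int:
    """Family target score on a gene set: binary = number of genes with at
    least one site; site_count = total number of sites."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in utr_index]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) without UTRs excluded from scoring")
    counts = [len(seed_sites(utr_index[g], family, g))
              for g in genes if g in utr_index]
    if mode == "binary":
        return int(sum(1 for c in counts if c > 0))
    if mode == "site_count":
        return int(sum(counts))
    raise ValueError(f"unknown scoring mode {mode!r}")


def _null_permutations(background, n_perm, rng):
    """N random orderings of the background; a null set of size k is the
    first k entries of an ordering, so null sets are nested in k."""
    B = len(background)
    perms = np.tile(np.arange(B), (n_perm, 1))
    return rng.permuted(perms, axis=1)


def empirical_pvalue(observed: float, set_size: int, family: MiRNAFamily,
                     background, utr_index: dict, n_perm: int = 1000,
                     seed: int | None = None, rng=None, mode: str = "binary",
                     set_id: str = "", null_perms=None,
                     per_gene=None) -> EnrichmentResult:
    """Add-one Monte-Carlo p-value for one family on one gene set.

    N random gene sets of identical size are drawn without replacement from
    the background; p = (1 + #{null score >= observed}) / (1 + N), so p is
    always positive and bounded below by 1/(N+1).
    """
    background = list(background)
    if len(background) <= set_size:
        raise ValueError("background must be larger than the gene set")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse")
    if rng is None:
        rng = np.random.default_rng(seed)
    if per_gene is None:
        per_gene = site_counts(family, {g: utr_index[g] for g in background})
    vals = per_gene.reindex(background).to_numpy(dtype=float)
    if mode == "binary":
        vals = (vals > 0).astype(float)
    if null_perms is None:
        null_perms = _null_permutations(background, n_perm, rng)
    null_scores = vals[null_perms[:, :set_size]].sum(axis=1)
    n_ge = int((null_scores >= observed).sum())
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return EnrichmentResult(family_id=family.family_id, set_id=set_id,
                            observed=float(observed), n_perm=n_perm,
                            n_ge=n_ge, pvalue=p,
                            neg_log10_p=float(-np.log10(p)))


def enrichment_matrix(families, interval_sets, background, utr_index: dict,
                      n_perm: int = 1000, seed: int = 0,
                      mode: str = "binary"):
    """-log10 empirical p for every family x interval cell.

    Null gene sets are drawn once per interval (seeded reproducibly from
    ``seed``) and shared across families, so the matrix is deterministic
    and family-order independent.  Returns (DataFrame families x intervals,
    list of EnrichmentResult).
    """
    if not families or not interval_sets:
        raise ValueError("need at least one family and one interval set")
    background = [g for g in background if g in utr_index]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(interval_sets))
    per_gene = {f.family_id: site_counts(f, {g: utr_index[g]
                                             for g in background})
                for f in families}
    results = []
    mat = pd.DataFrame(index=[f.family_id for f in families],
                       columns=[s.set_id for s in interval_sets], dtype=float)
    for child, gset in zip(children, interval_sets):
        rng = np.random.default_rng(child)
        genes_in_bg = [g for g in gset.genes if g in utr_index]
        null_perms = _null_permutations(background, n_perm, rng)
        for fam in families:
            obs = target_score(gset.genes, fam, utr_index, mode=mode)
            res = empirical_pvalue(
                obs, len(genes_in_bg), fam, background, utr_index,
                n_perm=n_perm, rng=rng, mode=mode, set_id=gset.set_id,
                null_perms=null_perms, per_gene=per_gene[fam.family_id],
            )
            results.append(res)
            mat.loc[fam.family_id, gset.set_id] = res.neg_log10_p
    return mat, results


def rank_master_regulators(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rank families by summed -log10 p across intervals, descending; ties
    broken lexicographically by family id."""
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("enrichment matrix contains non-finite values")
    summed = matrix.sum(axis=1)
    order = sorted(summed.index, key=lambda f: (-summed[f], f))
    return pd.DataFrame({
        "family_id": order,
        "summed_neg_log10_p": summed.reindex(order).to_numpy(),
        "rank": np.arange(1, len(order) + 1),
    })


def predicted_targets_in_sets(family: MiRNAFamily, interval_sets,
                              utr_index: dict) -> pd.DataFrame:
    """Genes that appear in >= 1 characteristic set and carry >= 1 seed site
    of the family, annotated with the intervals in which they appear."""
    hits: dict = {}
    for gset in interval_sets:
        for g in gset.genes:
            if g in utr_index and seed_sites(utr_index[g], family, g):
                hits.setdefault(g, []).append(gset.set_id)
    return pd.DataFrame({
        "gene": sorted(hits),
        "intervals": [",".join(hits[g]) for g in sorted(hits)],
    })
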