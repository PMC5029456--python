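"""Ground-truthed synthetic datasets for the estrogen-response pipeline.

Emulates the structure of a paired mRNA / small-RNA time course in an ER+
cell line: 10 time points (0--24 h after stimulation), three biological
replicates, negative-binomial counts, three temporal gene archetypes
(transient pulse, sustained induction, repression with optional partial
recovery) plus flat null genes, and an induced "master" miRNA whose seed
sites are planted into the 3'-UTRs of a chosen subset of responsive genes.

Every random draw is governed by a single seed in :class:`SimulationConfig`,
so an identical configuration reproduces a bit-identical dataset.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CLASS_LABELS = ("transient", "induced", "repressed", "null")

_DNA = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp_dna(s: str) -> str:
    """Reverse complement of a DNA string."""
    return "".join(_RC[c] for c in reversed(s))


def rna_to_dna(s: str) -> str:
    return s.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror the study design being emulated: 10 time points
    {0,1,2,3,4,5,6,8,12,24} h, 3 replicates, 600 genes split evenly over
    the three archetypes plus nulls, NB dispersion 0.05, amplitude 2, and
    one master miRNA reaching a sixfold induction by 24 h.
    """

    n_genes: int = 600
    class_fractions: dict = field(
        default_factory=lambda: {
            "transient": 0.25, "induced": 0.25, "repressed": 0.25, "null": 0.25,
        }
    )
    n_mirnas: int = 21
    n_master_mirnas: int = 1
    timepoints: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 12.0, 24.0)
    n_replicates: int = 3
    baseline_mean: float = 1000.0
    baseline_log_sd: float = 0.5
    dispersion: float = 0.05
    effect_size: float = 2.0
    master_fold: float = 6.0
    library_size_sd: float = 0.15
    utr_length_range: tuple = (200, 400)
    sites_per_target: int = 1
    n_targets: int = 30
    recovery_fraction: float = 0.5
    recovery_plateau: float = 0.6
    mirna_baseline_mean: float = 1000.0
    mirna_baseline_log_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        fracs = self.class_fractions
        if set(fracs) != set(CLASS_LABELS):
            raise ValueError(f"class_fractions must have keys {CLASS_LABELS}")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp[0] != 0.0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("n_genes", "n_mirnas", "n_master_mirnas", "n_replicates",
                     "sites_per_target"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_master_mirnas > self.n_mirnas:
            raise ValueError("n_master_mirnas must be <= n_mirnas")
        if self.baseline_mean <= 0 or self.mirna_baseline_mean <= 0:
            raise ValueError("baseline means must be positive")
        if self.effect_size <= 0 or self.master_fold <= 0:
            raise ValueError("effect sizes must be positive")
        lo, hi = self.utr_length_range
        if lo < 40 or hi < lo:
            raise ValueError("utr_length_range must satisfy 40 <= lo <= hi")

    def class_counts(self) -> dict:
        """Deterministic largest-remainder apportionment of genes to classes."""
        raw = {k: self.class_fractions[k] * self.n_genes for k in CLASS_LABELS}
        counts = {k: int(math.floor(v)) for k, v in raw.items()}
        short = self.n_genes - sum(counts.values())
        # hand leftover genes to the largest fractional remainders, ties by label
        order = sorted(CLASS_LABELS, key=lambda k: (-(raw[k] - counts[k]), k))
        for k in order[:short]:
            counts[k] += 1
        return counts


@dataclass
class GroundTruth:
    """What was planted: per-gene class and archetype parameters, responsive
    flags, master miRNA identities, and planted target-site positions."""

    classes: dict                 # gene -> class label
    archetype_params: dict        # gene -> dict of archetype parameters
    responsive_genes: list        # genes with a non-null archetype
    gene_baselines: dict          # gene -> latent baseline mean
    master_mirnas: list           # miRNA ids of planted masters
    responsive_mirnas: list       # miRNA ids with a non-flat latent profile
    planted_targets: dict = field(default_factory=dict)  # gene -> [site starts]

    def to_json(self) -> str:
        payload = {
            "classes": self.classes,
            "archetype_params": self.archetype_params,
            "responsive": self.responsive_genes,
            "gene_baselines": self.gene_baselines,
            "master_mirnas": self.master_mirnas,
            "responsive_mirnas": self.responsive_mirnas,
            "planted_targets": self.planted_targets,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            classes=d["classes"],
            archetype_params=d["archetype_params"],
            responsive_genes=d["responsive"],
            gene_baselines=d["gene_baselines"],
            master_mirnas=d["master_mirnas"],
            responsive_mirnas=d["responsive_mirnas"],
            planted_targets=d["planted_targets"],
        )


# ---------------------------------------------------------------------------
# latent archetype trajectories
# ---------------------------------------------------------------------------

def transient_mean(t, baseline, amplitude, peak, width):
    """Gaussian pulse: baseline * (1 + a * exp(-(t-p)^2 / (2 w^2)))."""
    t = np.asarray(t, dtype=float)
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return baseline * (1.0 + amplitude * np.exp(-((t - peak) ** 2) / (2.0 * width**2)))


def induced_mean(t, baseline, amplitude, k, h, t_final):
    """Hill induction normalized so the relative change at ``t_final`` equals
    ``amplitude`` exactly: baseline * (1 + a * g(t)/g(t_final))."""
    t = np.asarray(t, dtype=float)
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    g = t**h / (t**h + k**h)
    gf = t_final**h / (t_final**h + k**h)
    return baseline * (1.0 + amplitude * g / gf)


def repressed_mean(t, baseline, drop, recovery, tau_fast=0.5, tau_rec=6.0):
    """Repression with partial recovery.

    A fast initial drop of fractional amplitude ``drop`` (a < 1) followed by
    a slow recovery toward the plateau baseline*(1 - a + a*r); recovery=0
    gives monotone repression.  drop=0.5 with recovery=0.6 plateaus at
    0.8*baseline; a GATA3-like profile (plateau at 60% of time zero) uses
    e.g. drop=0.6, recovery=1/3.
    """
    t = np.asarray(t, dtype=float)
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if drop >= 1.0:
        raise ValueError("repressed drop amplitude must be < 1 (mean would go negative)")
    return baseline * (
        1.0
        - drop * (1.0 - np.exp(-t / tau_fast))
        + drop * recovery * (1.0 - np.exp(-t / tau_rec))
    )


def _gene_ids(n: int):
    return [f"g{i:04d}" for i in range(n)]


def _mirna_ids(n: int):
    return [f"syn-mir-{i:03d}" for i in range(n)]


def generate_gene_profiles(config: SimulationConfig):
    """Latent mean matrix (genes x timepoints) plus the ground truth.

    Archetype parameters are drawn per gene: transient pulses peak at a
    measured time point in [2, 6] h with width <= peak/3 (so the pulse has
    decayed at t=0); induced genes follow a Hill curve normalized to reach
    the configured relative change exactly at the last time point; repressed
    genes drop by 1 - 1/effect_size, with a configurable fraction following
    a GATA3-like partial recovery to ``recovery_plateau`` of baseline.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    tp = np.asarray(config.timepoints, dtype=float)
    genes = _gene_ids(config.n_genes)
    counts = config.class_counts()

    labels = []
    for lab in CLASS_LABELS:
        labels.extend([lab] * counts[lab])
    classes = dict(zip(genes, labels))

    mu_log = math.log(config.baseline_mean) - config.baseline_log_sd**2 / 2.0
    baselines = np.exp(rng.normal(mu_log, config.baseline_log_sd, size=config.n_genes))

    es = config.effect_size
    a_rep = 1.0 - 1.0 / es
    a_rec = min(0.9, a_rep + 0.1)
    r_rec = (config.recovery_plateau - 1.0 + a_rec) / a_rec
    peak_choices = [t for t in tp if 2.0 <= t <= 6.0] or [tp[len(tp) // 2]]

    means = np.empty((config.n_genes, tp.size))
    params: dict = {}
    for i, g in enumerate(genes):
        b = float(baselines[i])
        lab = classes[g]
        if lab == "transient":
            peak = float(rng.choice(peak_choices))
            width = float(rng.uniform(0.75, max(0.76, min(2.0, peak / 3.0))))
            params[g] = {"class": lab, "peak": peak, "width": width, "amplitude": es}
            means[i] = transient_mean(tp, b, es, peak, width)
        elif lab == "induced":
            k = float(rng.uniform(2.0, 5.0))
            h = float(rng.uniform(1.5, 3.0))
            params[g] = {"class": lab, "k": k, "h": h, "amplitude": es}
            means[i] = induced_mean(tp, b, es, k, h, float(tp[-1]))
        elif lab == "repressed":
            recovers = bool(rng.random() < config.recovery_fraction)
            drop, rec = (a_rec, r_rec) if recovers else (a_rep, 0.0)
            params[g] = {"class": lab, "drop": drop, "recovery": rec,
                         "plateau": 1.0 - drop + drop * rec}
            means[i] = repressed_mean(tp, b, drop, rec)
        else:
            params[g] = {"class": lab}
            means[i] = np.full(tp.size, b)

    truth = GroundTruth(
        classes=classes,
        archetype_params=params,
        responsive_genes=[g for g in genes if classes[g] != "null"],
        gene_baselines={g: float(b) for g, b in zip(genes, baselines)},
        master_mirnas=[],
        responsive_mirnas=[],
    )
    mean_df = pd.DataFrame(means, index=genes, columns=tp)
    return mean_df, truth


def generate_mirna_profiles(config: SimulationConfig):
    """Latent miRNA means: masters follow a Hill induction reaching
    ``master_fold`` (as a ratio to time zero) exactly at the final time
    point; all other miRNAs are flat."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    tp = np.asarray(config.timepoints, dtype=float)
    mirnas = _mirna_ids(config.n_mirnas)
    masters = mirnas[: config.n_master_mirnas]

    mu_log = math.log(config.mirna_baseline_mean) - config.mirna_baseline_log_sd**2 / 2.0
    baselines = np.exp(
        rng.normal(mu_log, config.mirna_baseline_log_sd, size=config.n_mirnas)
    )
    # keep masters comfortably expressed so the RPMM filter retains them
    baselines[: config.n_master_mirnas] = np.maximum(
        baselines[: config.n_master_mirnas], config.mirna_baseline_mean
    )

    means = np.tile(baselines[:, None], (1, tp.size))
    for j in range(config.n_master_mirnas):
        # k=8, h=2 yields a ~2x ratio by 4 h on the way to the final fold
        means[j] = induced_mean(tp, baselines[j], config.master_fold - 1.0,
                                8.0, 2.0, float(tp[-1]))
    truth_masters = list(masters)
    mean_df = pd.DataFrame(means, index=mirnas, columns=tp)
    return mean_df, truth_masters


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------

def sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in config.timepoints:
        for r in range(1, config.n_replicates + 1):
            rows.append({"sample_id": f"t{t:g}_r{r}", "time_h": float(t),
                         "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def library_size_factors(config: SimulationConfig, n_samples: int, spawn_key: int):
    """Per-sample log-normal depth multipliers (sigma = library_size_sd)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(spawn_key,))
    )
    return np.exp(rng.normal(0.0, config.library_size_sd, size=n_samples))


def sample_counts(means: pd.DataFrame, config: SimulationConfig, *,
                  size_factors=None, spawn_key: int = 1) -> pd.DataFrame:
    """Draw NB counts with mean m = sf_s * mu_g(t) and Var = m + alpha m^2.

    ``means`` is genes x timepoints; each timepoint column is expanded to
    ``n_replicates`` samples.  dispersion 0 falls back to Poisson sampling.
    """
    if (np.asarray(means) < 0).any():
        raise ValueError("latent means must be non-negative")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(spawn_key,))
    )
    meta = sample_metadata(config)
    if size_factors is None:
        size_factors = library_size_factors(config, len(meta), spawn_key + 10)
    m = means[meta["time_h"].to_numpy()].to_numpy(dtype=float)
    m = m * np.asarray(size_factors)[None, :]
    alpha = config.dispersion
    if alpha == 0:
        counts = rng.poisson(m)
    else:
        r = 1.0 / alpha
        p = r / (r + m)
        counts = rng.negative_binomial(r, p)
    return pd.DataFrame(counts.astype(np.int64), index=means.index,
                        columns=meta.index)


# ---------------------------------------------------------------------------
# miRNA sequences, families, and UTRs with planted seed sites
# ---------------------------------------------------------------------------

def family_site_patterns(seed_rna: str) -> dict:
    """DNA match patterns for the three canonical site classes of a 7-nt
    extended seed (miRNA nucleotides 2-8, RNA 5'->3')."""
    seed = rna_to_dna(seed_rna)
    if len(seed) != 7 or any(c not in "ACGT" for c in seed):
        raise ValueError(f"invalid seed sequence: {seed_rna!r}")
    rc7 = revcomp_dna(seed)          # 7mer-m8 core
    return {"8mer": rc7 + "A", "7mer-m8": rc7, "7mer-1A": rc7[1:] + "A"}


def generate_mirna_table(config: SimulationConfig) -> pd.DataFrame:
    """Random 22-nt mature miRNA sequences with mutually distinct extended
    seeds; no family's site patterns occur inside another family's 8mer."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
    rna = np.array(list("ACGU"))
    rows = []
    seeds_seen: set = set()
    site8s: list = []
    attempts = 0
    while len(rows) < config.n_mirnas:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not generate distinct miRNA families")
        mature = "".join(rng.choice(rna, size=22))
        seed = mature[1:8]
        if seed in seeds_seen:
            continue
        pats = family_site_patterns(seed)
        # avoid pattern collisions between families inside planted sites
        if any(pats["7mer-m8"] in s8 or pats["7mer-1A"] in s8 for s8 in site8s):
            continue
        if any(p8 in pats["8mer"] for p8 in site8s):
            continue
        seeds_seen.add(seed)
        site8s.append(pats["8mer"])
        rows.append({"mirna_id": _mirna_ids(config.n_mirnas)[len(rows)],
                     "family_id": f"fam-{seed}", "mature_sequence": mature})
    return pd.DataFrame(rows)


def _scan_any(seq: str, patterns) -> list:
    """All (start, end) spans in ``seq`` matching any pattern (overlaps kept)."""
    spans = []
    for pat in patterns:
        start = 0
        while True:
            i = seq.find(pat, start)
            if i < 0:
                break
            spans.append((i, i + len(pat)))
            start = i + 1
    return spans


def generate_utrs(config: SimulationConfig, truth: GroundTruth,
                  mirna_table: pd.DataFrame, max_attempts: int = 200):
    """3'-UTR sequences: i.i.d. uniform ACGT background, rejection-sampled so
    no seed match to any configured family occurs, except ``sites_per_target``
    8mer sites of the master family planted at recorded positions in each
    planted target gene.

    Mutates ``truth.planted_targets`` with the 0-based site start positions.
    Returns a dict gene -> DNA string.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(4,)))
    fam_by_mirna = mirna_table.set_index("mirna_id")
    master_seeds = [
        fam_by_mirna.loc[m, "mature_sequence"][1:8] for m in truth.master_mirnas
    ]
    all_patterns = []
    for seq in mirna_table["mature_sequence"]:
        pats = family_site_patterns(seq[1:8])
        all_patterns.extend([pats["7mer-m8"], pats["7mer-1A"]])

    site8 = {s: family_site_patterns(s)["8mer"] for s in master_seeds}
    lo, hi = config.utr_length_range
    site_len = 8
    if lo < site_len * config.sites_per_target + 2 * config.sites_per_target:
        raise ValueError("UTR length range too short for planted sites")

    # choose planted targets: responsive genes, balanced across archetypes
    by_class: dict = {"transient": [], "induced": [], "repressed": []}
    for g in truth.responsive_genes:
        by_class[truth.classes[g]].append(g)
    targets: list = []
    i = 0
    while len(targets) < min(config.n_targets, len(truth.responsive_genes)):
        lab = ("transient", "induced", "repressed")[i % 3]
        pool = by_class[lab]
        if pool:
            j = int(rng.integers(len(pool)))
            targets.append(pool.pop(j))
        i += 1

    utrs: dict = {}
    truth.planted_targets = {}
    genes = list(truth.classes)
    for g in genes:
        L = int(rng.integers(lo, hi + 1))
        planted_spans: list = []
        if g in targets:
            # non-overlapping planted positions with a 1-nt margin
            positions: list = []
            for _ in range(1000):
                pos = int(rng.integers(0, L - site_len + 1))
                if all(abs(pos - q) >= site_len + 1 for q in positions):
                    positions.append(pos)
                if len(positions) == config.sites_per_target:
                    break
            else:
                raise RuntimeError(f"could not place sites in UTR of {g}")
            positions.sort()
            planted_spans = [(p, p + site_len) for p in positions]
            truth.planted_targets[g] = positions
        seq = rng.choice(_DNA, size=L)
        master_site = site8[master_seeds[0]] if master_seeds else ""
        for p, q in planted_spans:
            seq[p:q] = list(master_site)
        planted_idx = np.zeros(L, dtype=bool)
        for p, q in planted_spans:
            planted_idx[p:q] = True
        ok = False
        for _ in range(max_attempts):
            s = "".join(seq)
            bad = np.zeros(L, dtype=bool)
            for a, b in _scan_any(s, all_patterns):
                span_planted = (a >= 0 and b <= L and planted_idx[a:b].all())
                if not span_planted:
                    bad[a:b] = True
            bad &= ~planted_idx
            if not bad.any():
                ok = True
                break
            seq[bad] = rng.choice(_DNA, size=int(bad.sum()))
        if not ok:
            raise RuntimeError(
                f"failed to purge accidental seed matches from UTR of {g} "
                f"after {max_attempts} attempts"
            )
        utrs[g] = "".join(seq)
    return utrs


# ---------------------------------------------------------------------------
# whole-dataset orchestration and on-disk format
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    mrna_counts: pd.DataFrame        # genes x samples, int
    mirna_counts: pd.DataFrame       # miRNAs x samples, int
    metadata: pd.DataFrame           # sample_id -> time_h, replicate
    utrs: dict                       # gene -> DNA string
    mirna_table: pd.DataFrame        # mirna_id, family_id, mature_sequence
    truth: GroundTruth
    gene_means: pd.DataFrame
    mirna_means: pd.DataFrame


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full dataset deterministically from the config seed."""
    config.validate()
    gene_means, truth = generate_gene_profiles(config)
    mirna_means, masters = generate_mirna_profiles(config)
    truth.master_mirnas = masters
    truth.responsive_mirnas = list(masters) if config.master_fold != 1.0 else []
    meta = sample_metadata(config)
    sf = library_size_factors(config, len(meta), 6)
    mrna_counts = sample_counts(gene_means, config, size_factors=sf, spawn_key=1)
    mirna_counts = sample_counts(mirna_means, config, size_factors=sf, spawn_key=5)
    mirna_table = generate_mirna_table(config)
    utrs = generate_utrs(config, truth, mirna_table)
    return SyntheticDataset(
        config=config,
        mrna_counts=mrna_counts,
        mirna_counts=mirna_counts,
        metadata=meta,
        utrs=utrs,
        mirna_table=mirna_table,
        truth=truth,
        gene_means=gene_means,
        mirna_means=mirna_means,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write the dataset as plain-text files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna_counts": out / "mrna_counts.tsv",
        "mirna_counts": out / "mirna_counts.tsv",
        "metadata": out / "metadata.tsv",
        "utrs": out / "utrs.fasta",
        "mirnas": out / "mirnas.tsv",
        "truth": out / "truth.json",
    }
    try:
        dataset.mrna_counts.rename_axis("feature_id").to_csv(
            paths["mrna_counts"], sep="\t")
        dataset.mirna_counts.rename_axis("feature_id").to_csv(
            paths["mirna_counts"], sep="\t")
        dataset.metadata.reset_index().to_csv(paths["metadata"], sep="\t",
                                              index=False)
        records = [SeqRecord(Seq(s), id=g, description="") for g, s in
                   dataset.utrs.items()]
        SeqIO.write(records, paths["utrs"], "fasta")
        dataset.mirna_table.to_csv(paths["mirnas"], sep="\t", index=False)
        paths["truth"].write_text(dataset.truth.to_json())
    except OSError as exc:
        raise OSError(f"failed writing dataset file: {exc.filename}: {exc}") from exc
    return {k: str(v) for k, v in paths.items()}


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int64)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t").set_index("sample_id")
    meta["time_h"] = meta["time_h"].astype(float)
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def read_utrs(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_mirna_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
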