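"""End-to-end orchestration: configuration, stage wiring, input validation,
logging, deterministic seeding, and the run manifest.

Stages run in the order the analysis is defined: differential expression
against time zero -> responsive-gene selection and timepoint census ->
temporal clustering into three classes -> characteristic directions over
consecutive intervals -> miRNA expression calls -> family-level target-site
enrichment -> master-regulator ranking.  A master seed fans out to
per-stage seeds through numpy's SeedSequence spawning (a splitmix-style
derivation), so any stage can be re-run independently and the whole run is
checksum-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chardir, clustering, diffexpr, enrichment, mirna, simulate

logger = logging.getLogger("estrodyn")


def setup_logging(out_dir=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler()]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(level=level, format="%(asctime)s %(name)s %(message)s",
                        handlers=handlers, force=True)


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the pipeline; defaults are the analysis'
    published operating points (mean normalized count >= 500, adjusted
    p < 0.05, twofold mRNA change; 50 RPMM, 1.5-fold, uncorrected p <= 0.05
    for miRNAs; three clusters; 1000 Monte-Carlo permutations)."""

    # inputs
    mrna_counts: str = ""
    mirna_counts: str = ""
    metadata: str = ""
    utrs: str = ""
    mirnas: str = ""
    out_dir: str = "estrodyn_out"
    # mRNA thresholds
    min_mean_mrna: float = 500.0
    min_abs_log2fc: float = 1.0
    alpha_adj: float = 0.05
    pseudocount: float = 0.5
    # miRNA thresholds
    min_rpmm: float = 50.0
    fc_mirna: float = 1.5
    alpha_mirna: float = 0.05
    # clustering
    k: int = 3
    wavelet: str = "db3"
    linkage: str = "ward"
    grid_step_h: float = 1.0
    label_delta: float = 0.1
    # characteristic direction
    gamma: float = 0.5
    selection_rule: str = "cumulative_energy"
    theta: float = 0.5
    top_n: int | None = None
    # enrichment
    n_perm: int = 1000
    score_mode: str = "binary"
    length_match: bool = False
    # seeding
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_mean_mrna", "min_abs_log2fc", "alpha_adj",
                     "min_rpmm", "fc_mirna", "alpha_mirna", "theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_stage(path: Path, writer) -> None:
    """Write through a .partial file, renamed only on success."""
    partial = path.with_suffix(path.suffix + ".partial")
    writer(partial)
    partial.replace(path)


@dataclass
class ValidationReport:
    fatal: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(paths: dict) -> ValidationReport:
    """Referential-integrity checks across the input bundle.

    Fatal: unreadable files, samples without metadata, malformed UTR
    sequences, malformed miRNA sequences.  Warned: genes without UTRs.
    """
    report = ValidationReport()
    loaded = {}
    readers = {
        "mrna_counts": simulate.read_counts,
        "mirna_counts": simulate.read_counts,
        "metadata": simulate.read_metadata,
        "utrs": simulate.read_utrs,
        "mirnas": simulate.read_mirna_table,
    }
    for key, reader in readers.items():
        p = paths.get(key)
        if not p or not Path(p).exists():
            report.fatal.append(f"missing input file for {key}: {p}")
            continue
        try:
            loaded[key] = reader(p)
        except Exception as exc:
            report.fatal.append(f"unreadable {key} ({p}): {exc}")
    if report.fatal:
        return report

    meta = loaded["metadata"]
    for key in ("mrna_counts", "mirna_counts"):
        missing = [s for s in loaded[key].columns if s not in meta.index]
        if missing:
            report.fatal.append(f"{key} samples without metadata: {missing}")
    if (meta["time_h"] == 0.0).sum() < 2:
        report.fatal.append("fewer than 2 replicates at time zero")
    utrs = loaded["utrs"]
    for g, s in utrs.items():
        if not set(s.upper()) <= set("ACGTU"):
            report.fatal.append(f"UTR of {g} contains non-ACGTU characters")
    no_utr = [g for g in loaded["mrna_counts"].index if g not in utrs]
    if no_utr:
        report.warnings.append(
            f"{len(no_utr)} gene(s) in counts without UTRs (excluded from "
            f"enrichment): {no_utr[:5]}{'...' if len(no_utr) > 5 else ''}"
        )
    tab = loaded["mirnas"]
    for col in ("mirna_id", "family_id", "mature_sequence"):
        if col not in tab.columns:
            report.fatal.append(f"miRNA table lacks column {col!r}")
    return report


def run_simulate(sim_config: simulate.SimulationConfig, out_dir) -> dict:
    """Generate and write a synthetic dataset plus its manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate.generate_dataset(sim_config)
    paths = simulate.write_dataset(ds, out)
    manifest = {
        "config": dataclasses.asdict(sim_config),
        "checksums": {k: _sha256(Path(v)) for k, v in paths.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True, default=str))
    return paths


def run_full(config: PipelineConfig, dataset=None) -> dict:
    """Execute every stage; returns a summary dict (also written to disk).

    ``dataset`` may be a pre-built SyntheticDataset; otherwise inputs are
    read from the paths in the config.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    t_start = time.time()
    try:
        if dataset is not None:
            counts = dataset.mrna_counts
            mirna_counts = dataset.mirna_counts
            meta = dataset.metadata
            utrs = dataset.utrs
            mirna_table = dataset.mirna_table
        else:
            counts = simulate.read_counts(config.mrna_counts)
            mirna_counts = simulate.read_counts(config.mirna_counts)
            meta = simulate.read_metadata(config.metadata)
            utrs = simulate.read_utrs(config.utrs)
            mirna_table = simulate.read_mirna_table(config.mirnas)

        stage = "de"
        logger.info("differential expression vs time zero")
        de = diffexpr.run_de(counts, meta, pseudocount=config.pseudocount)
        _write_stage(out / "de_table.tsv", de.to_tsv)

        stage = "responsive"
        responsive = diffexpr.select_responsive_genes(
            de, config.min_mean_mrna, config.min_abs_log2fc, config.alpha_adj)
        logger.info("responsive genes: %d", len(responsive.genes))

        stage = "cluster"
        classes_by_gene: dict = {}
        census_hist = None
        if len(responsive.genes) >= config.k:
            lfc = de.table.pivot(index="gene", columns="time_h",
                                 values="log2fc").loc[responsive.genes]
            lfc.insert(0, 0.0, 0.0)
            times = np.array(sorted(lfc.columns))
            lfc = lfc[times]
            grid = np.arange(times.min(), times.max() + 1e-9,
                             config.grid_step_h)
            assignment = clustering.cluster_trajectories(
                lfc, times, k=config.k, grid=grid, method=config.linkage,
                delta=config.label_delta)
            classes_by_gene = assignment.classes().to_dict()
            _write_stage(out / "clusters.tsv",
                         lambda p: assignment.to_frame().to_csv(p, sep="\t",
                                                                index=False))
            _write_stage(out / "centroids.tsv",
                         lambda p: assignment.centroids.to_csv(p, sep="\t"))
            _write_stage(
                out / "dendrogram.nwk",
                lambda p: Path(p).write_text(clustering.dendrogram_newick(
                    assignment.linkage_matrix, lfc.index)))
            _, census_hist, _ = diffexpr.census_timepoints(
                de, responsive, classes_by_gene)
        resp_frame = responsive.to_frame(classes_by_gene)
        _write_stage(out / "responsive_genes.tsv",
                     lambda p: resp_frame.to_csv(p, sep="\t", index=False))

        stage = "chardir"
        norm = diffexpr.normalize(counts, de.size_factors)
        analyzed = norm.index[norm.mean(axis=1) >= config.min_mean_mrna]
        interval_sets = chardir.consecutive_interval_sets(
            norm.loc[analyzed], meta, gamma=config.gamma,
            rule=config.selection_rule, theta=config.theta,
            top_n=config.top_n)
        directions = chardir.consecutive_interval_directions(
            norm.loc[analyzed], meta, gamma=config.gamma)
        for d, s in zip(directions, interval_sets):
            _write_stage(out / f"chardir_{s.set_id}.tsv",
                         lambda p, d=d, s=s: chardir.direction_table(d, s)
                         .to_csv(p, sep="\t", index=False,
                                 float_format="%.6g"))

        stage = "mirna"
        rpmm = mirna.rpmm_normalize(mirna_counts)
        response = mirna.test_response(
            rpmm, meta, thresholds=(config.fc_mirna, 2.0),
            alpha=config.alpha_mirna, min_mean=config.min_rpmm)
        _write_stage(out / "mirna_response.tsv", response.to_tsv)

        stage = "enrich"
        families = enrichment.group_families(mirna_table, rpmm,
                                             min_mean=config.min_rpmm)
        background = [g for g in analyzed if g in utrs]
        matrix, _results = enrichment.enrichment_matrix(
            families, interval_sets, background, utrs,
            n_perm=config.n_perm, seed=config.seed, mode=config.score_mode)
        _write_stage(out / "enrichment_matrix.tsv",
                     lambda p: matrix.to_csv(p, sep="\t",
                                             float_format="%.6g"))

        stage = "rank"
        ranking = enrichment.rank_master_regulators(matrix)
        _write_stage(out / "ranking.tsv",
                     lambda p: ranking.to_csv(p, sep="\t", index=False,
                                              float_format="%.6g"))
        top_family = ranking["family_id"].iloc[0]
        top_targets = enrichment.predicted_targets_in_sets(
            next(f for f in families if f.family_id == top_family),
            interval_sets, utrs)
        _write_stage(out / "top_family_targets.tsv",
                     lambda p: top_targets.to_csv(p, sep="\t", index=False))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    class_counts = pd.Series(classes_by_gene).value_counts().to_dict() \
        if classes_by_gene else {}
    summary = {
        "schema_version": 1,
        "n_genes": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_responsive_genes": len(responsive.genes),
        "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
        "timepoint_census": {int(k): int(v) for k, v in census_hist.items()}
        if census_hist is not None else {},
        "n_expressed_mirnas": len(response.expressed),
        "responsive_mirnas": {
            str(thr): ids for thr, ids in response.responsive.items()
        },
        "n_families_tested": len(families),
        "top_families": ranking.head(5).to_dict(orient="records"),
        "seed": config.seed,
    }
    _write_stage(out / "summary.json",
                 lambda p: Path(p).write_text(json.dumps(summary, indent=1,
                                                         sort_keys=True)))

    outputs = sorted(p for p in out.iterdir()
                     if p.is_file() and p.suffix != ".partial"
                     and p.name not in ("manifest.json", "run.log"))
    checksums = {p.name: _sha256(p) for p in outputs}
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t_start, 3),
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True, default=str))
    summary["checksums"] = checksums
    return summary
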