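"""End-to-end model-search-and-preparation runs and score-table triage.

``run_prepare`` ties the stages together: database preprocessing and
redundancy reduction, hit filtering, pairwise-alignment extraction, domain
clustering, homologue editing, superposition and ensemble truncation, with
the results written under ``search_<job>/models/domain_<n>/ensembles/``.
Each stage's counts land in the run report; failures surface with the stage
name and partial outputs are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import search_clustering as sc
from .ensembling import DEFAULT_STEP, build_ensembles
from .errors import PipelineStageError
from .io_formats import (read_fasta, read_hit_table, read_pdb, read_stockholm,
                         write_ensemble_pdb, write_fasta, write_pdb,
                         write_pir_pairwise)
from .model_editing import EditProtocol, apply_protocol
from .assessment import SolutionScores, rank_solutions
from .seqdata import SequenceRecord
from .superposition import superpose_to_centroid

logger = logging.getLogger("mrprep")


@dataclass
class RunConfig:
    """Pipeline defaults; each one mirrors the documented default behaviour."""

    score_cutoff: float = sc.DEFAULT_SCORE_CUTOFF       # hit-score cutoff (20)
    redundancy_level: int = 95                          # sequence-db redundancy %
    mid_tol: int = sc.DEFAULT_MID_TOL                   # domain midpoint tolerance
    ext_tol: int = sc.DEFAULT_EXT_TOL                   # domain extent tolerance
    truncation_step: int = DEFAULT_STEP                 # ensemble step %
    protocol: EditProtocol = EditProtocol.CGAMMA_MIXED
    mean_residue_mass: float = 110.0                    # Da
    seed: int = 0
    output_dir: Path = Path("mrprep_out")
    job_id: str = "1"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not isinstance(self.protocol, EditProtocol):
            self.protocol = EditProtocol(self.protocol)


@dataclass
class PrepareReport:
    """Per-stage counts and output locations for one preparation run."""

    root: str = ""
    n_db_records: int = 0
    n_after_preprocess: int = 0
    n_after_redundancy: int = 0
    n_hits: int = 0
    n_hits_kept: int = 0
    n_domains: int = 0
    models_per_domain: dict[int, int] = field(default_factory=dict)
    ensembles_per_domain: dict[int, int] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - surfaced with stage name
            raise PipelineStageError(name, exc) from exc
    return wrap


def run_prepare(config: RunConfig,
                target_fasta: str | Path,
                db_fasta: str | Path,
                msa_sto: str | Path,
                hit_table: str | Path,
                structures_dir: str | Path) -> PrepareReport:
    """Run the model-search-and-preparation stages over file inputs.

    ``structures_dir`` must contain ``<hit id>.pdb`` for every hit that is to
    be edited.  Returns the report; the output tree is written under
    ``config.output_dir / search_<job_id>``.
    """
    report = PrepareReport()
    root = config.output_dir / f"search_{config.job_id}"
    models_root = root / "models"
    models_root.mkdir(parents=True, exist_ok=True)
    report.root = str(root)

    handler = logging.FileHandler(root / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("defaults: score_cutoff=%s redundancy=%s mid_tol=%s ext_tol=%s "
                    "step=%s protocol=%s seed=%s",
                    config.score_cutoff, config.redundancy_level, config.mid_tol,
                    config.ext_tol, config.truncation_step, config.protocol.value,
                    config.seed)
        target = _stage("read-target")(lambda: read_fasta(Path(target_fasta).read_text())[0])

        db = _stage("read-db")(lambda: read_fasta(Path(db_fasta).read_text()))
        report.n_db_records = len(db)
        db = _stage("preprocess")(sc.preprocess_sequence_db, db)
        report.n_after_preprocess = len(db)
        db = _stage("redundancy")(sc.reduce_redundancy, db, config.redundancy_level)
        report.n_after_redundancy = len(db)
        kept_ids = {rec.id for rec in db}
        logger.info("database: %d records, %d after preprocessing, %d at %d%% redundancy",
                    report.n_db_records, report.n_after_preprocess,
                    report.n_after_redundancy, config.redundancy_level)

        hits = _stage("read-hits")(lambda: read_hit_table(Path(hit_table).read_text()))
        report.n_hits = len(hits)
        hits = _stage("filter-hits")(sc.filter_hits, hits, config.score_cutoff)
        hits = [h for h in hits if h.id in kept_ids]
        report.n_hits_kept = len(hits)
        logger.info("hits: %d scored, %d kept at cutoff %.1f",
                    report.n_hits, report.n_hits_kept, config.score_cutoff)
        if not hits:
            logger.info("no hits survive filtering; nothing to prepare")
            _write_report(root, report)
            return report

        msa = _stage("read-msa")(lambda: read_stockholm(Path(msa_sto).read_text()))
        for hit in hits:
            hit.alignment = _stage("extract-alignments")(
                sc.extract_pairwise, msa, target.id, hit.id)
            hit.midpoint, hit.extent = _stage("spans")(sc.hit_span, hit.alignment)
        clusters = _stage("cluster-domains")(
            sc.cluster_domains, hits, config.mid_tol, config.ext_tol)
        report.n_domains = len(clusters)
        logger.info("clustered %d hits into %d domain(s)", len(hits), len(clusters))

        structures_dir = Path(structures_dir)
        for cluster in clusters:
            domain_dir = models_root / f"domain_{cluster.number}"
            ensembles_dir = domain_dir / "ensembles"
            ensembles_dir.mkdir(parents=True, exist_ok=True)
            edited = []
            for hit in cluster.members:
                pdb_path = structures_dir / f"{hit.id}.pdb"
                if not pdb_path.exists():
                    report.errors.append(f"domain {cluster.number}: no structure for {hit.id}")
                    logger.warning("no structure file for hit %s; skipped", hit.id)
                    continue
                model = _stage("read-structures")(
                    lambda p=pdb_path, h=hit: read_pdb(p.read_text(), model_id=h.id))
                model = _stage("sculpt")(apply_protocol, model, hit.alignment, config.protocol)
                edited.append(model)
                (domain_dir / f"{hit.id}.pdb").write_text(write_pdb(model))
                (domain_dir / f"{hit.id}.fasta").write_text(write_fasta([
                    SequenceRecord(target.id, hit.alignment.target_row),
                    SequenceRecord(hit.id, hit.alignment.hit_row),
                ]))
                (domain_dir / f"{hit.id}.pir").write_text(write_pir_pairwise(
                    target.id, hit.alignment.target_row, hit.id, hit.alignment.hit_row))
            report.models_per_domain[cluster.number] = len(edited)
            if len(edited) < 2:
                report.ensembles_per_domain[cluster.number] = 0
                logger.info("domain %d: %d model(s); too few to ensemble",
                            cluster.number, len(edited))
                continue
            superposed = _stage("superpose")(superpose_to_centroid, edited)
            ensembles = _stage("ensembles")(
                build_ensembles, superposed, config.truncation_step, cluster.number)
            for ens in ensembles:
                name = f"ensemble_{ens.level.label}.pdb"
                (ensembles_dir / name).write_text(write_ensemble_pdb(ens))
            report.ensembles_per_domain[cluster.number] = len(ensembles)
            logger.info("domain %d: %d models, %d ensembles (core %d residues)",
                        cluster.number, len(edited), len(ensembles),
                        len(superposed.core_positions))
        _write_report(root, report)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_report(root: Path, report: PrepareReport) -> None:
    (root / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")


_TSV_COLUMNS = ("model_id", "phaser_llg", "phaser_tfz", "molrep_rf_sigma",
                "molrep_tf_sigma", "r_work", "r_free", "shelxe_cc", "shelxe_acl")


def read_scores_tsv(path: str | Path) -> list[SolutionScores]:
    """Read a tab-separated score table (columns named as the score fields)."""
    frame = pd.read_csv(path, sep="\t")
    if "model_id" not in frame.columns:
        raise ValueError("score table needs a 'model_id' column")
    scores = []
    for _, row in frame.iterrows():
        kwargs = {"model_id": str(row["model_id"])}
        for col in _TSV_COLUMNS[1:]:
            if col in frame.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        scores.append(SolutionScores(**kwargs))
    return scores


def run_assess(config: RunConfig, scores_tsv: str | Path,
               out_tsv: str | Path | None = None) -> pd.DataFrame:
    """Triage a score table into the ranked summary (optionally written as TSV)."""
    ranked = rank_solutions(read_scores_tsv(scores_tsv))
    if out_tsv is not None:
        Path(out_tsv).parent.mkdir(parents=True, exist_ok=True)
        ranked.to_csv(out_tsv, sep="\t", index=False)
    for _, row in ranked.iterrows():
        logger.info("%-20s R_free=%-8s %s", row["model_id"],
                    "-" if pd.isna(row["r_free"]) else f"{row['r_free']:.3f}",
                    row["category"])
    return ranked
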