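"""Pipeline orchestration: configuration, stage order, outputs.

Stage order: [screen transcripts ->] merge databases -> similarity search
-> chain hits into loci -> select full-length loci -> matched regions ->
spliced gene models -> classify -> resolve overlaps -> write outputs.
Given identical inputs and configuration the run is deterministic: two
runs produce byte-identical files, and the thread setting never changes
results (parallelism, when used, only fans out independent per-locus work
and merges in a fixed order).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import gtf
from .alignment import GenomeAssembly, SearchParams, search_hits
from .loci import (CandidateLocus, FullLengthRule, MatchedRegion,
                   build_matched_regions, chain_hits, classify_locus)
from .models import (GeneModel, ModelRejection, assign_ids, extract_region,
                     finalize_model, resolve_overlaps)
from .screening import ScreenParams, read_transcripts, screen_transcripts
from .spliced import SpliceParams, spliced_align
from .toxindb import ToxinDatabase, merge_databases, read_fasta_db, write_fasta_db

logger = logging.getLogger(__name__)


class InputError(Exception):
    """Unreadable, empty, or malformed input (CLI exit code 2)."""


@dataclass
class Config:
    """All pipeline knobs, serializable to/from YAML and echoed in the log."""

    max_gene_size: int = 50_000
    min_cds_len: int = 200
    min_identity: float = 0.80
    cluster_threshold: float = 0.99
    full_length_min_coverage: float = 0.95
    full_length_end_tolerance: int = 10
    seed_k: int = 11
    search_match: int = 2
    search_mismatch: int = -3
    search_gap_open: int = -5
    search_gap_extend: int = -2
    search_min_score: float = 50.0
    splice_match: int = 5
    splice_mismatch: int = -4
    splice_gap_open: int = -12
    splice_gap_extend: int = -2
    splice_intron_cost: int = -40
    min_intron: int = 50
    flank: int = 500
    rescue_codons: int = 30
    overlap_min_frac: float = 0.30
    screen_min_coverage: float = 0.50
    join_penalty: float = 10.0
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.cluster_threshold <= 1:
            raise ValueError("cluster_threshold must be in (0, 1]")
        if self.max_gene_size <= 0 or self.min_cds_len < 3:
            raise ValueError("size thresholds out of range")

    def search_params(self) -> SearchParams:
        return SearchParams(k=self.seed_k, match=self.search_match,
                            mismatch=self.search_mismatch,
                            gap_open=self.search_gap_open,
                            gap_extend=self.search_gap_extend,
                            min_score=self.search_min_score,
                            min_identity=self.min_identity)

    def splice_params(self) -> SpliceParams:
        return SpliceParams(match=self.splice_match, mismatch=self.splice_mismatch,
                            gap_open=self.splice_gap_open,
                            gap_extend=self.splice_gap_extend,
                            intron_cost=self.splice_intron_cost,
                            min_intron=self.min_intron,
                            max_intron=self.max_gene_size)

    def full_length_rule(self) -> FullLengthRule:
        return FullLengthRule(min_coverage=self.full_length_min_coverage,
                              end_tolerance=self.full_length_end_tolerance)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class AnnotationResult:
    models: list[GeneModel]
    matched_regions: list[MatchedRegion]
    rejections: list[ModelRejection]
    loci: list[CandidateLocus]


def annotate_genome(genome: GenomeAssembly, db: ToxinDatabase,
                    config: Config | None = None) -> AnnotationResult:
    """Run search -> chain -> select -> gene models -> classify -> dedupe in memory."""
    config = config or Config()
    if len(db) == 0:
        raise InputError("empty toxin database")
    hits = search_hits(db, genome, config.search_params())
    logger.info("stage=search queries=%d hits=%d", len(db), len(hits))
    qlen = {r.id: r.length for r in db}
    loci = chain_hits(hits, config.max_gene_size, qlen, config.join_penalty)
    rule = config.full_length_rule()
    full = []
    for locus in loci:
        locus.status = classify_locus(locus, qlen[locus.query_id], rule)
        if locus.status == "full_length":
            full.append(locus)
    logger.info("stage=chain loci=%d full_length=%d", len(loci), len(full))
    regions = build_matched_regions(full)
    logger.info("stage=matched_regions regions=%d", len(regions))
    models: list[GeneModel] = []
    rejections: list[ModelRejection] = []
    sp = config.splice_params()
    for locus in full:
        region, mapping = extract_region(genome, locus, config.flank)
        query = db.get(locus.query_id)
        aln = spliced_align(query.cds, region, sp)
        if aln is None or not aln.segments:
            rejections.append(ModelRejection(locus.query_id, locus.contig_id,
                                             "no_spliced_alignment"))
            continue
        result = finalize_model(aln, query, mapping, region,
                                config.min_cds_len, config.rescue_codons)
        if isinstance(result, ModelRejection):
            rejections.append(result)
        else:
            models.append(result)
    final = assign_ids(resolve_overlaps(models, config.overlap_min_frac))
    n_warn = sum(1 for m in final if m.status == "warning")
    logger.info("stage=gene_models built=%d rejected=%d final=%d reliable=%d warning=%d",
                len(models), len(rejections), len(final), len(final) - n_warn, n_warn)
    return AnnotationResult(models=final, matched_regions=regions,
                            rejections=rejections, loci=loci)


def run_pipeline(genome_path, database_paths, transcripts_path=None,
                 config: Config | None = None, outdir="toxannot_out",
                 proteins_path=None) -> Path:
    """File-level entry point; writes all outputs into ``outdir``."""
    config = config or Config()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("toxannot")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        for key, val in sorted(asdict(config).items()):
            logger.info("config %s=%s", key, val)
        try:
            genome = GenomeAssembly.from_fasta(genome_path)
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot read genome: {exc}") from exc
        if isinstance(database_paths, (str, Path)):
            database_paths = [database_paths]
        dbs = []
        for p in database_paths:
            try:
                dbs.append(read_fasta_db(p, config.min_cds_len))
            except OSError as exc:
                raise InputError(f"cannot read database: {exc}") from exc
        db = dbs[0]
        for extra in dbs[1:]:
            db = merge_databases(db, extra)
        if transcripts_path is not None:
            try:
                transcripts = read_transcripts(transcripts_path)
            except (OSError, ValueError) as exc:
                raise InputError(f"cannot read transcripts: {exc}") from exc
            custom = screen_transcripts(
                transcripts, db,
                ScreenParams(min_identity=config.min_identity,
                             min_coverage=config.screen_min_coverage,
                             min_cds_len=config.min_cds_len),
                config.search_params())
            logger.info("stage=screen transcripts=%d custom_records=%d",
                        len(transcripts), len(custom))
            write_fasta_db(custom, out / "custom_database.fasta")
            db = merge_databases(db, custom)
        if len(db) == 0:
            raise InputError("toxin database is empty after validation")
        logger.info("stage=database records=%d", len(db))
        result = annotate_genome(genome, db, config)
        gtf.write_annotation_gtf(result.models, out / "toxin_annotation.gtf")
        gtf.write_matched_regions_gtf(result.matched_regions, out / "matched_regions.gtf")
        gtf.write_cds_fasta(result.models, out / "toxins_cds.fasta")
        gtf.write_peptide_fasta(result.models, out / "toxins_pep.fasta")
        gtf.write_warnings(result.models, out / "annotation_warning.txt")
        if proteins_path is not None:
            from Bio import SeqIO

            from .models import best_match_report
            proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(proteins_path), "fasta")}
            rows = best_match_report(result.models, proteins)
            with open(out / "best_match.tsv", "w") as fh:
                fh.write("model_id\tsubject\tidentity\tcoverage\n")
                for row in rows:
                    fh.write(f"{row['model_id']}\t{row['subject']}\t"
                             f"{row['identity']}\t{row['coverage']}\n")
            logger.info("stage=best_match subjects=%d models=%d", len(proteins), len(rows))
        config.to_yaml(out / "config_used.yaml")
        logger.info("stage=write outdir=%s models=%d", out, len(result.models))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
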