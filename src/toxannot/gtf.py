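"""GTF2.2 emission and reading for annotation outputs.

All internal coordinates are 0-based half-open; conversion to the GTF
1-based inclusive convention happens here and only here. The reader is
strict and dialect-locked to what the writer emits (plus plain CDS-bearing
reference GTFs), so write -> read -> write is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import ReferenceGene
from .loci import MatchedRegion
from .models import GeneModel
from .toxindb import parse_family

SOURCE = "toxannot"


def _attrs(pairs: list[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_annotation_gtf(models: list[GeneModel], path) -> None:
    """One ``transcript`` line per model and one ``CDS`` line per exon.

    The frame column of each CDS line is the exon's phase; coordinates are
    1-based inclusive. Models sorted by (contig, start, id).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n")
        for m in sorted(models, key=lambda m: (m.contig_id, m.start, m.end, m.id)):
            attrs = _attrs([("gene_id", m.id), ("transcript_id", m.id),
                            ("family", m.family), ("status", m.status),
                            ("source_query", m.source_query)])
            fh.write("\t".join([m.contig_id, SOURCE, "transcript", str(m.start + 1),
                                str(m.end), f"{m.score:.1f}", m.strand, ".", attrs]) + "\n")
            for (s, e), phase in zip(m.exons, m.phases):
                fh.write("\t".join([m.contig_id, SOURCE, "CDS", str(s + 1), str(e),
                                    f"{m.score:.1f}", m.strand, str(phase), attrs]) + "\n")


def write_matched_regions_gtf(regions: list[MatchedRegion], path) -> None:
    """One ``match`` line per region; score = best identity x 100."""
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n")
        for i, r in enumerate(sorted(regions, key=lambda r: (r.contig_id, r.start, r.end)), 1):
            attrs = _attrs([("region_id", f"region_{i}"),
                            ("queries", ",".join(r.query_ids))])
            fh.write("\t".join([r.contig_id, SOURCE, "match", str(r.start + 1),
                                str(r.end), f"{r.best_identity * 100:.1f}", r.strand,
                                ".", attrs]) + "\n")


def write_cds_fasta(models: list[GeneModel], path) -> None:
    _write_fasta(path, [(m.id, m.cds) for m in
                        sorted(models, key=lambda m: (m.contig_id, m.start, m.end, m.id))])


def write_peptide_fasta(models: list[GeneModel], path) -> None:
    _write_fasta(path, [(m.id, m.peptide) for m in
                        sorted(models, key=lambda m: (m.contig_id, m.start, m.end, m.id))])


def _write_fasta(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_warnings(models: list[GeneModel], path) -> None:
    """One line per warning model: id, contig, 1-based interval, reason."""
    with open(path, "w") as fh:
        fh.write("#id\tcontig\tinterval\treason\n")
        for m in sorted(models, key=lambda m: (m.contig_id, m.start, m.end, m.id)):
            if m.status != "warning":
                continue
            fh.write(f"{m.id}\t{m.contig_id}\t{m.start + 1}-{m.end}\tpremature_stop_codon\n")


@dataclass(frozen=True)
class GtfFeature:
    contig_id: str
    source: str
    feature: str
    start: int  # converted to 0-based half-open
    end: int
    score: str
    strand: str
    frame: str
    attributes: dict[str, str]


def read_gtf(path) -> list[GtfFeature]:
    feats: list[GtfFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            attrs: dict[str, str] = {}
            for chunk in parts[8].split(";"):
                chunk = chunk.strip()
                if not chunk:
                    continue
                key, _, val = chunk.partition(" ")
                attrs[key] = val.strip().strip('"')
            feats.append(GtfFeature(parts[0], parts[1], parts[2], int(parts[3]) - 1,
                                    int(parts[4]), parts[5], parts[6], parts[7], attrs))
    return feats


def read_reference_genes(path) -> list[ReferenceGene]:
    """Group CDS features of a GTF/GFF reference by transcript_id into gene footprints."""
    groups: dict[str, list[GtfFeature]] = {}
    for f in read_gtf(path):
        if f.feature != "CDS":
            continue
        tid = f.attributes.get("transcript_id") or f.attributes.get("gene_id")
        if tid is None:
            raise ValueError("CDS feature without transcript_id/gene_id")
        groups.setdefault(tid, []).append(f)
    genes = []
    for tid, feats in sorted(groups.items()):
        fam = feats[0].attributes.get("family") or parse_family(tid)
        genes.append(ReferenceGene(
            gene_id=tid, family=fam, contig_id=feats[0].contig_id,
            strand=feats[0].strand,
            start=min(f.start for f in feats), end=max(f.end for f in feats),
        ))
    return genes


def read_annotation_models(path) -> dict[str, dict]:
    """Exon structure per transcript from an annotation GTF (transcription order)."""
    out: dict[str, dict] = {}
    for f in read_gtf(path):
        if f.feature != "CDS":
            continue
        tid = f.attributes["transcript_id"]
        rec = out.setdefault(tid, {"contig_id": f.contig_id, "strand": f.strand,
                                   "exons": [], "phases": [],
                                   "attributes": f.attributes})
        rec["exons"].append((f.start, f.end))
        rec["phases"].append(f.frame)
    for rec in out.values():
        order = sorted(range(len(rec["exons"])), key=lambda i: rec["exons"][i][0],
                       reverse=(rec["strand"] == "-"))
        rec["exons"] = [rec["exons"][i] for i in order]
        rec["phases"] = [rec["phases"][i] for i in order]
    return out


def spliced_cds_from_gtf(genome, model: dict) -> str:
    """Re-extract and splice a model's CDS from the genome (round-trip check)."""
    from .alignment import revcomp

    contig = genome.contigs[model["contig_id"]]
    parts = [contig[s:e] for s, e in model["exons"]]
    if model["strand"] == "-":
        parts = [revcomp(p) for p in parts]
    return "".join(parts)
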