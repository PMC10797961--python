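"""Screening assembled venom-tissue transcripts for full-length toxin CDSs.

Transcripts with a similarity hit to the toxin database contribute the ORF
best overlapping the hit footprint as a new custom database record,
labelled with the family of the best database hit. The resulting custom
database complements the main one (the integration that gives the best
annotation recovery).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

from .alignment import GenomeAssembly, SearchParams, revcomp, search_hits
from .toxindb import (STOP_CODONS, ToxinDatabase, ToxinRecord, validate_cds)


@dataclass(frozen=True)
class TranscriptRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty transcript")
        if not set(self.sequence) <= set("ACGTN"):
            raise ValueError("transcript alphabet outside ACGTN")


@dataclass(frozen=True)
class OrfCall:
    """A full ATG->stop open reading frame on a transcript.

    Coordinates are 0-based half-open on the transcript's forward strand;
    ``cds`` is the reading-direction sequence including the stop codon.
    """

    transcript_id: str
    strand: str
    start: int
    end: int
    cds: str
    frame: int


def read_transcripts(path) -> list[TranscriptRecord]:
    return [TranscriptRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def find_orfs(t: TranscriptRecord, min_len: int = 200) -> list[OrfCall]:
    """All ATG->stop ORFs of length >= min_len in all 6 frames.

    Nested ORFs sharing a stop codon report only the longest (first ATG
    after the previous in-frame stop).
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    calls: list[OrfCall] = []
    n = len(t.sequence)
    for strand in "+-":
        seq = t.sequence if strand == "+" else revcomp(t.sequence)
        for frame in range(3):
            atg = None
            for p in range(frame, len(seq) - 2, 3):
                codon = seq[p : p + 3]
                if codon in STOP_CODONS:
                    if atg is not None:
                        length = p + 3 - atg
                        if length >= min_len:
                            s, e = atg, p + 3
                            if strand == "-":
                                s, e = n - e, n - s
                            calls.append(OrfCall(t.id, strand, s, e,
                                                 seq[atg : p + 3], frame))
                    atg = None
                elif codon == "ATG" and atg is None:
                    atg = p
    calls.sort(key=lambda c: (c.start, c.end, c.strand, c.frame))
    return calls


@dataclass
class ScreenParams:
    min_identity: float = 0.80
    min_coverage: float = 0.50  # of the database entry
    min_cds_len: int = 200


def screen_transcripts(ts: list[TranscriptRecord], db: ToxinDatabase,
                       params: ScreenParams | None = None,
                       search_params: SearchParams | None = None) -> ToxinDatabase:
    """Build a custom database from transcripts similar to known toxins.

    For each transcript with a hit at identity >= ``min_identity`` covering
    >= ``min_coverage`` of the database entry, the ORF best overlapping the
    hit footprint is emitted with the best hit's family (ties broken by
    identity then id). Exact-duplicate CDSs are deduplicated.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    params = params or ScreenParams()
    sp = search_params or SearchParams(min_identity=params.min_identity)
    if not ts:
        return ToxinDatabase(records=[], source="custom")
    pseudo_genome = GenomeAssembly(contigs={t.id: t.sequence for t in ts})
    hits = search_hits(db, pseudo_genome, sp)
    qlen = {r.id: r.length for r in db}
    best_hit: dict[str, object] = {}
    for h in hits:
        if h.identity < params.min_identity:
            continue
        if (h.qend - h.qstart) / qlen[h.query_id] < params.min_coverage:
            continue
        cur = best_hit.get(h.contig_id)
        if (cur is None or (h.score, h.identity) > (cur.score, cur.identity)
                or ((h.score, h.identity) == (cur.score, cur.identity)
                    and h.query_id < cur.query_id)):
            best_hit[h.contig_id] = h
    families = {r.id: r.family for r in db}
    records: list[ToxinRecord] = []
    seen: set[str] = set()
    for t in ts:
        h = best_hit.get(t.id)
        if h is None:
            continue
        orfs = find_orfs(t, params.min_cds_len)
        best = None
        for orf in orfs:
            if orf.strand != h.strand:
                continue
            ov = max(0, min(orf.end, h.tend) - max(orf.start, h.tstart))
            key = (ov, len(orf.cds))
            if ov > 0 and (best is None or key > best[0]):
                best = (key, orf)
        if best is None:
            continue
        orf = best[1]
        if not validate_cds(orf.cds, params.min_cds_len).valid:
            continue
        if orf.cds in seen:
            continue
        seen.add(orf.cds)
        records.append(ToxinRecord(id=f"{t.id}|{families[h.query_id]}",
                                   family=families[h.query_id], cds=orf.cds))
    return ToxinDatabase(records=records, source="custom")
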