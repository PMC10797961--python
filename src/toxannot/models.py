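"""Gene models: region extraction, finalization, classification, deduplication.

A gene model is an ordered exon chain on the genome whose spliced sequence
is a full-length CDS. Models whose spliced alignment does not land exactly
on a canonical start/stop are rescued by a bounded in-frame scan; models
that cannot be rescued are rejected and their locus remains visible only in
the matched-regions output. A model with a premature in-frame stop codon is
kept but flagged ``warning`` (candidate truncated paralog or pseudogene).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .alignment import GenomeAssembly, revcomp
from .loci import CandidateLocus
from .spliced import SplicedAlignment
from .toxindb import STOP_CODONS, ToxinRecord

START_CODON = "ATG"


@dataclass
class RegionMapping:
    """Converts oriented region coordinates back to forward-strand genome coordinates."""

    contig_id: str
    strand: str
    g_start: int  # forward-strand genomic interval backing the region
    g_end: int

    def interval(self, r_start: int, r_end: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.g_start + r_start, self.g_start + r_end
        return self.g_end - r_end, self.g_end - r_start

    def position(self, r: int) -> int:
        if self.strand == "+":
            return self.g_start + r
        return self.g_end - 1 - r


def extract_region(genome: GenomeAssembly, locus: CandidateLocus,
                   flank: int = 500) -> tuple[str, RegionMapping]:
    """Oriented region around the locus span (reverse-complemented for strand -)."""
    contig = genome.contigs[locus.contig_id]
    if locus.span_start < 0 or locus.span_end > len(contig):
        raise ValueError("locus span outside contig")
    g_start = max(0, locus.span_start - flank)
    g_end = min(len(contig), locus.span_end + flank)
    seq = contig[g_start:g_end]
    if locus.strand == "-":
        seq = revcomp(seq)
    return seq, RegionMapping(locus.contig_id, locus.strand, g_start, g_end)


@dataclass
class GeneModel:
    id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, transcription order
    phases: list[int]
    cds: str
    peptide: str
    status: str  # reliable | warning
    source_query: str
    family: str
    score: float
    identity: float

    @property
    def start(self) -> int:
        return min(e[0] for e in self.exons)

    @property
    def end(self) -> int:
        return max(e[1] for e in self.exons)


@dataclass
class ModelRejection:
    locus_query: str
    contig_id: str
    reason: str


def translate(cds: str) -> str:
    """Standard-code translation; terminal stop omitted, internal stops as ``*``."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not a codon multiple")
    pep = str(Seq(cds).translate())
    if pep.endswith("*"):
        pep = pep[:-1]
    return pep


def classify_annotation(model: GeneModel) -> str:
    """``warning`` iff the CDS carries >= 1 in-frame internal stop codon."""
    cds = model.cds
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return "warning"
    return "reliable"


def _scan_start(region: str, t_start: int, t_end: int, rescue_codons: int) -> int | None:
    """Offset d (multiple of 3, |d| <= 3*rescue_codons) such that the codon at
    ``t_start + d`` is ATG; smallest |d| wins, ties prefer upstream extension."""
    for a in range(0, 3 * rescue_codons + 1, 3):
        for d in ((-a, a) if a else (0,)):
            s = t_start + d
            if s < 0 or s + 3 > t_end:
                continue
            if region[s : s + 3] == START_CODON:
                return d
    return None


def _scan_stop(region: str, t_end: int, t_start: int, cds_len: int,
               rescue_codons: int) -> int | None:
    """Offset e with (cds_len + e) % 3 == 0 such that the last codon at
    ``t_end + e`` is a stop; smallest |e| wins, ties prefer trimming."""
    limit = 3 * rescue_codons
    best = None
    for e in range(-limit, limit + 1):
        if (cds_len + e) % 3 != 0:
            continue
        end = t_end + e
        if end - 3 < t_start or end > len(region):
            continue
        if region[end - 3 : end] in STOP_CODONS:
            key = (abs(e), e > 0)
            if best is None or key < best[0]:
                best = (key, e)
    return None if best is None else best[1]


def finalize_model(aln: SplicedAlignment, cds_query: ToxinRecord, mapping: RegionMapping,
                   region: str, min_cds_len: int = 200,
                   rescue_codons: int = 30) -> GeneModel | ModelRejection:
    """Turn a spliced alignment into a genome-anchored gene model.

    The first/last exon boundaries are adjusted by a bounded in-frame scan
    so the spliced CDS begins with ATG and ends with a canonical stop;
    rejection (typed, not raised) if no such adjustment exists or the final
    CDS is too short / not a codon multiple.
    """
    segs = [[s.t_start, s.t_end] for s in aln.segments]
    if not segs:
        return ModelRejection(cds_query.id, mapping.contig_id, "empty_alignment")

    if region[segs[0][0] : segs[0][0] + 3] != START_CODON:
        d = _scan_start(region, segs[0][0], segs[0][1], rescue_codons)
        if d is None:
            return ModelRejection(cds_query.id, mapping.contig_id, "no_start_codon")
        segs[0][0] += d

    cds_len = sum(e - s for s, e in segs)
    last = segs[-1]
    cur_stop = region[last[1] - 3 : last[1]] if cds_len % 3 == 0 else ""
    if cur_stop not in STOP_CODONS or cds_len % 3 != 0:
        e = _scan_stop(region, last[1], last[0], cds_len, rescue_codons)
        if e is None:
            return ModelRejection(cds_query.id, mapping.contig_id, "no_stop_codon")
        last[1] += e
        cds_len += e

    if cds_len % 3 != 0:
        return ModelRejection(cds_query.id, mapping.contig_id, "not_codon_multiple")
    if cds_len < min_cds_len:
        return ModelRejection(cds_query.id, mapping.contig_id, "below_min_cds_len")
    if any(e - s <= 0 for s, e in segs):
        return ModelRejection(cds_query.id, mapping.contig_id, "degenerate_exon")

    cds = "".join(region[s:e] for s, e in segs)
    phases = []
    cum = 0
    for s, e in segs:
        phases.append((3 - cum % 3) % 3)
        cum += e - s
    exons = [mapping.interval(s, e) for s, e in segs]
    model = GeneModel(
        id="", contig_id=mapping.contig_id, strand=mapping.strand,
        exons=exons, phases=phases, cds=cds, peptide=translate(cds),
        status="", source_query=cds_query.id, family=cds_query.family,
        score=aln.score, identity=aln.identity,
    )
    model.status = classify_annotation(model)
    return model


def _footprint_overlap(a: GeneModel, b: GeneModel) -> int:
    """Total overlap of the two models' exon unions (genomic bp)."""
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def resolve_overlaps(models: list[GeneModel], min_frac: float = 0.30) -> list[GeneModel]:
    """Keep the best model among same-strand models whose CDS footprints
    overlap by more than ``min_frac`` of the shorter footprint.

    Best by (score, identity, CDS length, then lexicographically smallest
    source query id); deterministic and invariant to input order.
    """
    ranked = sorted(models, key=lambda m: (-m.score, -m.identity, -len(m.cds),
                                           m.source_query, m.contig_id, m.start))
    kept: list[GeneModel] = []
    for m in ranked:
        m_len = sum(e - s for s, e in m.exons)
        clash = False
        for k in kept:
            if k.contig_id != m.contig_id or k.strand != m.strand:
                continue
            ov = _footprint_overlap(m, k)
            k_len = sum(e - s for s, e in k.exons)
            if ov > min_frac * min(m_len, k_len):
                clash = True
                break
        if not clash:
            kept.append(m)
    kept.sort(key=lambda m: (m.contig_id, m.start, m.end, m.source_query))
    return kept


def assign_ids(models: list[GeneModel]) -> list[GeneModel]:
    """Stable per-family ids in genomic order (SVMP-1, SVMP-2, ...)."""
    counts: dict[str, int] = {}
    for m in sorted(models, key=lambda m: (m.contig_id, m.start, m.end, m.source_query)):
        counts[m.family] = counts.get(m.family, 0) + 1
        m.id = f"{m.family}-{counts[m.family]}"
    return models


def best_match_report(models: list[GeneModel], proteins: dict[str, str]) -> list[dict]:
    """Best protein-space match of each model peptide against a user protein set."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    rows = []
    for m in models:
        pep = m.peptide.replace("*", "X")
        best = None
        for sid in sorted(proteins):
            alns = aligner.align(proteins[sid], pep)
            if len(alns) == 0:
                continue
            aln = alns[0]
            tb, qb = aln.aligned
            if len(qb) == 0:
                continue
            matched = sum(
                1
                for (ts, te), (qs, qe) in zip(tb, qb)
                for a, b in zip(proteins[sid][ts:te], pep[qs:qe])
                if a == b
            )
            cols = sum(te - ts for ts, te in tb)
            ident = matched / cols if cols else 0.0
            cov = (qb[-1][1] - qb[0][0]) / len(pep) if pep else 0.0
            key = (aln.score, ident)
            if best is None or key > best[0]:
                best = (key, sid, ident, cov)
        if best is not None:
            rows.append({"model_id": m.id, "subject": best[1],
                         "identity": round(best[2], 4), "coverage": round(best[3], 4)})
        else:
            rows.append({"model_id": m.id, "subject": "NA", "identity": 0.0, "coverage": 0.0})
    return rows
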