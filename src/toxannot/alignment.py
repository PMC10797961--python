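"""Local alignment of toxin CDSs against genome contigs.

The search contract is BLAST-like: for every query CDS, report all gapped
local alignments (hits) above identity and score thresholds. The engine is
a seed-and-extend design: an exact k-mer index over the genome supplies
seeds, seeds are grouped into diagonal bands (one band per putative exon),
and each band is extended with a gapped local alignment. A tabular adapter
lets precomputed hits from an external aligner be substituted.

Coordinates are 0-based half-open on the forward strand everywhere inside
the package; query coordinates are always in query-forward orientation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from Bio import Align, SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> 2-bit code; N deliberately unmapped (handled via mask)
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """A multi-contig genome: map contig id -> nucleotide string (ACGTN)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not set(seq) <= set("ACGTN"):
                raise ValueError(f"contig {cid}: alphabet outside ACGTN")

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self.contigs.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeAssembly":
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not contigs:
            raise ValueError(f"no sequences in {path}")
        return cls(contigs=contigs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for cid, seq in self.contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


@dataclass(frozen=True)
class LocalHit:
    """One local alignment of a query CDS against a contig."""

    query_id: str
    contig_id: str
    strand: str  # "+" or "-"
    qstart: int
    qend: int
    tstart: int
    tend: int
    identity: float
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError("bad query interval")
        if not (0 <= self.tstart < self.tend):
            raise ValueError("bad target interval")
        if not (0 < self.identity <= 1):
            raise ValueError("identity out of (0,1]")
        if self.score <= 0:
            raise ValueError("score must be positive")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass
class SearchParams:
    """Knobs of the similarity search (engine-defined defaults)."""

    k: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score: float = 50.0
    min_identity: float = 0.80
    # seed banding
    max_diag_drift: int = 20
    max_seed_gap: int = 150
    min_seeds: int = 2
    # extension window = seed extent +/- pad; a small pad bounds boundary
    # overshoot below the chaining overlap allowance
    window_pad: int = 12
    end_anchor: int = 8  # hits must start/end with this many exact matches


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer; -1 where the window contains N."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    bad = (win < 0).any(axis=1)
    codes[bad] = -1
    return codes


class SeedIndex:
    """Exact k-mer -> genomic positions index over both strands.

    Forward k-mers are stored once per contig (sorted by code); a
    minus-strand lookup queries the reverse complement of the k-mer, so
    minus-strand occurrences are encoded as forward positions of
    reverse-complement seeds.
    """

    def __init__(self, genome: GenomeAssembly, k: int = 11):
        if not 4 <= k <= 31:
            raise ValueError("k must be in [4, 31]")
        if not genome.contigs:
            raise ValueError("empty genome")
        self.k = k
        self.genome = genome
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for cid, seq in genome.contigs.items():
            codes = _kmer_codes(seq, k)
            order = np.argsort(codes, kind="stable")
            self._index[cid] = (codes[order], order.astype(np.int64))

    def lookup_codes(self, cid: str, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_offsets, target_positions) of all exact seed matches."""
        codes_sorted, pos_sorted = self._index[cid]
        valid = query_codes >= 0
        lo = np.searchsorted(codes_sorted, query_codes, side="left")
        hi = np.searchsorted(codes_sorted, query_codes, side="right")
        counts = np.where(valid, hi - lo, 0)
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qoff = np.repeat(np.arange(len(query_codes)), counts)
        tpos = np.concatenate(
            [pos_sorted[l:h] for l, h, c in zip(lo, hi, counts) if c > 0]
        )
        return qoff, tpos

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """Positions of one k-mer on both strands: (contig, pos, strand)."""
        out = []
        for strand, km in (("+", kmer), ("-", revcomp(kmer))):
            codes = _kmer_codes(km, self.k)
            for cid in self.genome.contigs:
                qo, tp = self.lookup_codes(cid, codes)
                out.extend((cid, int(p), strand) for p in tp)
        return sorted(out)


def _make_aligner(match, mismatch, gap_open, gap_extend, mode="local") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def _alignment_stats(aln) -> tuple[int, int, int, int, int, int]:
    """(matches, columns, qstart, qend, tstart, tend) over aligned blocks.

    Columns between consecutive blocks count as max(query gap, target gap);
    terminal unaligned overhangs are excluded.
    """
    tblocks, qblocks = aln.aligned
    if len(qblocks) == 0:
        return 0, 0, 0, 0, 0, 0
    tseq, qseq = str(aln.target), str(aln.query)
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        columns += te - ts
        matches += sum(1 for a, b in zip(tseq[ts:te], qseq[qs:qe]) if a == b)
    for i in range(1, len(qblocks)):
        columns += max(tblocks[i][0] - tblocks[i - 1][1], qblocks[i][0] - qblocks[i - 1][1])
    return (matches, columns, int(qblocks[0][0]), int(qblocks[-1][1]),
            int(tblocks[0][0]), int(tblocks[-1][1]))


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns in an optimal global alignment.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1. Every
    alignment column counts in the denominator, gap columns included, so a
    length difference lowers identity. Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    aligner = _make_aligner(1, -1, -2, -1, mode="global")
    aln = aligner.align(a, b)[0]
    matches, _, *_ = _alignment_stats(aln)
    return matches / aln.length if aln.length else 0.0


def _band_clusters(qoff: np.ndarray, tpos: np.ndarray, params: SearchParams):
    """Group seed matches into diagonal bands (one band ~ one exon hit)."""
    diag = tpos - qoff
    order = np.lexsort((tpos, diag))
    qoff, tpos, diag = qoff[order], tpos[order], diag[order]
    clusters = []
    start = 0
    for i in range(1, len(qoff) + 1):
        if i == len(qoff) or (
            diag[i] - diag[i - 1] > params.max_diag_drift
            or (diag[i] == diag[i - 1] and tpos[i] - tpos[i - 1] > params.max_seed_gap)
            or (diag[i] != diag[i - 1] and tpos[i] - tpos[i - 1] > params.max_seed_gap)
        ):
            clusters.append((qoff[start:i], tpos[start:i]))
            start = i
    return clusters


def _columns_of(aln) -> list[tuple[int | None, int | None, bool]]:
    """Explicit alignment columns: (target index, query index, is_match)."""
    tblocks, qblocks = aln.aligned
    tseq, qseq = str(aln.target), str(aln.query)
    cols: list[tuple[int | None, int | None, bool]] = []
    for b, ((ts, te), (qs, qe)) in enumerate(zip(tblocks, qblocks)):
        if b > 0:
            for t in range(tblocks[b - 1][1], ts):
                cols.append((t, None, False))
            for q in range(qblocks[b - 1][1], qs):
                cols.append((None, q, False))
        for t, q in zip(range(ts, te), range(qs, qe)):
            cols.append((t, q, tseq[t] == qseq[q]))
    return cols


def _trim_to_anchors(cols, anchor: int):
    """Trim both ends so the hit begins/ends with ``anchor`` consecutive matches.

    Local extension can overshoot a true alignment boundary (e.g. an exon
    end) with a weakly positive mismatch-rich tail; anchoring the ends on
    exact-match runs removes such tails so downstream chaining sees clean
    query intervals.
    """
    n = len(cols)
    run = 0
    start = None
    for i in range(n):
        run = run + 1 if cols[i][2] else 0
        if run == anchor:
            start = i - anchor + 1
            break
    if start is None:
        return None
    run = 0
    for i in range(n - 1, -1, -1):
        run = run + 1 if cols[i][2] else 0
        if run == anchor:
            return cols[start : i + anchor]
    return None  # pragma: no cover - symmetric with forward scan


def _score_columns(cols, params: SearchParams) -> float:
    score = 0.0
    in_gap = False
    for t, q, m in cols:
        if t is None or q is None:
            score += params.gap_extend if in_gap else params.gap_open
            in_gap = True
        else:
            score += params.match if m else params.mismatch
            in_gap = False
    return score


def _extend_cluster(query: str, contig: str, qs_arr, ts_arr, params: SearchParams, aligner):
    k, pad = params.k, params.window_pad
    qlo = max(0, int(qs_arr.min()) - pad)
    qhi = min(len(query), int(qs_arr.max()) + k + pad)
    tlo = max(0, int(ts_arr.min()) - pad)
    thi = min(len(contig), int(ts_arr.max()) + k + pad)
    qsub, tsub = query[qlo:qhi], contig[tlo:thi]
    alns = aligner.align(tsub, qsub)
    if len(alns) == 0 or alns[0].score <= 0:
        return None
    cols = _trim_to_anchors(_columns_of(alns[0]), params.end_anchor)
    if not cols:
        return None
    matches = sum(1 for c in cols if c[2])
    qidx = [q for _, q, _ in cols if q is not None]
    tidx = [t for t, _, _ in cols if t is not None]
    if not qidx or not tidx:
        return None
    return (qlo + qidx[0], qlo + qidx[-1] + 1, tlo + tidx[0], tlo + tidx[-1] + 1,
            matches / len(cols), _score_columns(cols, params))


def _merge_raw_hits(raw: list[tuple]) -> list[tuple]:
    """Drop hits whose query AND target intervals overlap a better hit."""
    raw = sorted(raw, key=lambda h: -h[5])
    kept: list[tuple] = []
    for h in raw:
        qs, qe, ts, te = h[0], h[1], h[2], h[3]
        redundant = any(
            min(qe, k[1]) - max(qs, k[0]) > 0 and min(te, k[3]) - max(ts, k[2]) > 0
            for k in kept
        )
        if not redundant:
            kept.append(h)
    return kept


def search_hits(db, genome: GenomeAssembly, params: SearchParams | None = None) -> list[LocalHit]:
    """All gapped local alignments of every database CDS against the genome.

    Hits below ``min_identity`` or ``min_score`` are dropped; seed
    extensions overlapping on both query and target are merged (best score
    wins). Result sorted by (contig, tstart, query, strand).
    """
    params = params or SearchParams()
    if len(db) == 0:
        raise ValueError("empty database")
    index = SeedIndex(genome, params.k)
    aligner = _make_aligner(params.match, params.mismatch, params.gap_open, params.gap_extend)
    hits: list[LocalHit] = []
    for rec in db:
        for strand in "+-":
            qseq = rec.cds if strand == "+" else revcomp(rec.cds)
            qcodes = _kmer_codes(qseq, params.k)
            for cid, contig in genome.contigs.items():
                qoff, tpos = index.lookup_codes(cid, qcodes)
                if len(qoff) == 0:
                    continue
                raw = []
                for qs_arr, ts_arr in _band_clusters(qoff, tpos, params):
                    if len(qs_arr) < params.min_seeds:
                        continue
                    ext = _extend_cluster(qseq, contig, qs_arr, ts_arr, params, aligner)
                    if ext is not None:
                        raw.append(ext)
                for qs, qe, ts, te, ident, score in _merge_raw_hits(raw):
                    if ident < params.min_identity or score < params.min_score:
                        continue
                    if strand == "-":
                        qs, qe = len(qseq) - qe, len(qseq) - qs
                    hits.append(LocalHit(rec.id, cid, strand, qs, qe, ts, te, ident, score))
    hits.sort(key=lambda h: (h.contig_id, h.tstart, h.query_id, h.strand, h.qstart))
    return hits


# ---------------------------------------------------------------------------
# BLAST outfmt-6-style tabular adapter

_OUTFMT6 = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_hits_tsv(path) -> list[LocalHit]:
    """Ingest precomputed hits in BLAST outfmt-6 convention.

    Coordinates are 1-based inclusive; a minus-strand hit has sstart > send.
    Converted on read to the internal 0-based half-open forward convention.
    """
    hits = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            d = dict(zip(_OUTFMT6, row))
            qs, qe = int(d["qstart"]) - 1, int(d["qend"])
            ss, se = int(d["sstart"]), int(d["send"])
            if ss <= se:
                strand, ts, te = "+", ss - 1, se
            else:
                strand, ts, te = "-", se - 1, ss
            hits.append(LocalHit(d["qseqid"], d["sseqid"], strand, qs, qe, ts, te,
                                 float(d["pident"]) / 100.0, float(d["bitscore"])))
    hits.sort(key=lambda h: (h.contig_id, h.tstart, h.query_id, h.strand, h.qstart))
    return hits


def write_hits_tsv(hits: list[LocalHit], path) -> None:
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            if h.strand == "+":
                ss, se = h.tstart + 1, h.tend
            else:
                ss, se = h.tend, h.tstart + 1
            alen = max(h.qend - h.qstart, h.tend - h.tstart)
            mism = round((1 - h.identity) * alen)
            w.writerow([h.query_id, h.contig_id, f"{h.identity * 100:.2f}", alen, mism, 0,
                        h.qstart + 1, h.qend, ss, se, "0.0", f"{h.score:.1f}"])
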