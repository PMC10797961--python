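"""Chaining local hits into candidate toxin loci and selecting full-length ones.

A candidate locus is a collinear chain of hits of one query CDS on one
contig/strand whose genomic span stays below the maximum gene size
(default 50 kb). Only loci covering essentially the whole query CDS
("full-length") go on to gene-model building; every full-length locus is
also surfaced as a matched region for supervised inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import LocalHit


@dataclass
class FullLengthRule:
    """What counts as a full-length match of the query CDS."""

    min_coverage: float = 0.95
    end_tolerance: int = 10


@dataclass
class CandidateLocus:
    query_id: str
    contig_id: str
    strand: str
    hits: list[LocalHit]  # transcription order
    span_start: int
    span_end: int
    query_coverage: float
    score: float
    status: str = "partial"  # full_length | partial

    @property
    def best_identity(self) -> float:
        return max(h.identity for h in self.hits)


@dataclass
class MatchedRegion:
    contig_id: str
    strand: str
    start: int
    end: int
    query_ids: list[str]
    best_identity: float


MAX_QUERY_OVERLAP = 15  # bp of query-interval overlap tolerated between chained hits
JOIN_PENALTY = 10.0  # score units per chain join
GAP_PENALTY_PER_KB = 1.0  # per kb of genomic gap at a join; keeps tandem copies apart


def _compatible(prev: LocalHit, nxt: LocalHit, strand: str) -> bool:
    """Can ``nxt`` follow ``prev`` in transcription order?"""
    if nxt.qstart < prev.qstart or nxt.qend <= prev.qend:
        return False
    qov = prev.qend - nxt.qstart
    if qov > MAX_QUERY_OVERLAP:
        return False
    allowance = max(0, qov)
    if strand == "+":
        return nxt.tstart >= prev.tend - allowance and nxt.tend > prev.tend
    # minus strand: transcription runs toward decreasing forward coordinates
    return nxt.tend <= prev.tstart + allowance and nxt.tstart < prev.tstart


def _span(first: LocalHit, last: LocalHit, strand: str) -> tuple[int, int]:
    if strand == "+":
        return first.tstart, last.tend
    return last.tstart, first.tend


def _coverage(hits: list[LocalHit], query_len: int) -> float:
    ivs = sorted((h.qstart, h.qend) for h in hits)
    covered, cur_s, cur_e = 0, ivs[0][0], ivs[0][1]
    for s, e in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return min(1.0, covered / query_len)


def _join_cost(prev: LocalHit, nxt: LocalHit, strand: str, join_penalty: float,
               gap_penalty_per_kb: float) -> float:
    """Cost of joining two hits: flat penalty plus a mild genomic-gap term.

    The gap term (1 score unit per kb by default) is negligible across real
    introns but breaks the tie that would otherwise let a chain skip from
    one tandem-array copy into the next within the gene-size bound.
    """
    gap = (nxt.tstart - prev.tend) if strand == "+" else (prev.tstart - nxt.tend)
    return join_penalty + gap_penalty_per_kb * max(0, gap) / 1000.0


def _best_chain(hits: list[LocalHit], strand: str, max_gene_size: int,
                join_penalty: float,
                gap_penalty_per_kb: float = GAP_PENALTY_PER_KB) -> tuple[list[int], float]:
    """Maximum-score collinear chain under the span constraint.

    Sparse DP with Pareto states: for each hit we keep all (score, anchor)
    pairs not dominated by another (anchor = span coordinate of the chain's
    first hit, used to enforce the span bound exactly). Exact, so it agrees
    with brute-force subset enumeration.
    """
    order = sorted(range(len(hits)), key=lambda i: (hits[i].qstart, hits[i].qend,
                                                    hits[i].tstart, hits[i].tend))
    # Pareto front per hit: list of (score, anchor, prev_hit, prev_state)
    states: dict[int, list[tuple]] = {}
    for i in order:
        h = hits[i]
        anchor = h.tstart if strand == "+" else -h.tend  # chain-start coordinate
        cand = [(h.score, anchor, -1, -1)]
        for j in order:
            if j == i:
                break
            if not _compatible(hits[j], h, strand):
                continue
            cost = _join_cost(hits[j], h, strand, join_penalty, gap_penalty_per_kb)
            for si, (sc, anc, _, _) in enumerate(states.get(j, [])):
                end_coord = h.tend if strand == "+" else -h.tstart
                if end_coord - anc > max_gene_size:
                    continue
                cand.append((sc + h.score - cost, anc, j, si))
        # prune dominated states (higher score and later/equal anchor dominate)
        cand.sort(key=lambda s: (-s[0], -s[1]))
        front: list[tuple] = []
        best_anchor = None
        for st in cand:
            if best_anchor is None or st[1] > best_anchor:
                front.append(st)
                best_anchor = st[1]
        states[i] = front
    # best terminal state, deterministic tie-break
    best = None
    for i in order:
        for si, st in enumerate(states[i]):
            key = (st[0], -hits[i].tstart, -si)
            if best is None or key > best[0]:
                best = (key, i, si)
    chain: list[int] = []
    i, si = best[1], best[2]
    best_score = states[i][si][0]
    while i != -1:
        chain.append(i)
        _, _, i, si = states[i][si]
    chain.reverse()
    return chain, best_score


def chain_hits(hits: list[LocalHit], max_gene_size: int = 50_000,
               query_lengths: dict[str, int] | None = None,
               join_penalty: float = JOIN_PENALTY) -> list[CandidateLocus]:
    """Chain hits into candidate loci, one group per (query, contig, strand).

    Loci are extracted greedily by repeated maximum-score chaining; each
    hit belongs to at most one locus. Result sorted by (contig, start).
    """
    groups: dict[tuple, list[LocalHit]] = {}
    for h in hits:
        groups.setdefault((h.query_id, h.contig_id, h.strand), []).append(h)
    loci: list[CandidateLocus] = []
    for (qid, cid, strand), group in sorted(groups.items()):
        remaining = list(group)
        while remaining:
            idx, chain_score = _best_chain(remaining, strand, max_gene_size, join_penalty)
            chain = [remaining[i] for i in idx]
            used = set(idx)
            remaining = [h for i, h in enumerate(remaining) if i not in used]
            start, end = _span(chain[0], chain[-1], strand)
            qlen = (query_lengths or {}).get(qid) or max(h.qend for h in chain)
            loci.append(CandidateLocus(
                query_id=qid, contig_id=cid, strand=strand, hits=chain,
                span_start=start, span_end=end,
                query_coverage=_coverage(chain, qlen),
                score=chain_score,
            ))
    loci.sort(key=lambda l: (l.contig_id, l.span_start, l.span_end, l.query_id, l.strand))
    return loci


def classify_locus(locus: CandidateLocus, query_len: int,
                   rule: FullLengthRule | None = None) -> str:
    """``full_length`` iff the chain covers the query CDS end to end."""
    rule = rule or FullLengthRule()
    coverage = _coverage(locus.hits, query_len)
    first_q = min(h.qstart for h in locus.hits)
    last_q = max(h.qend for h in locus.hits)
    if (coverage >= rule.min_coverage and first_q <= rule.end_tolerance
            and last_q >= query_len - rule.end_tolerance):
        return "full_length"
    return "partial"


def build_matched_regions(loci: list[CandidateLocus]) -> list[MatchedRegion]:
    """Merge overlapping full-length loci (same contig/strand) into maximal regions."""
    by_key: dict[tuple, list[CandidateLocus]] = {}
    for l in loci:
        by_key.setdefault((l.contig_id, l.strand), []).append(l)
    regions: list[MatchedRegion] = []
    for (cid, strand), group in sorted(by_key.items()):
        group.sort(key=lambda l: (l.span_start, l.span_end))
        cur: list[CandidateLocus] = []
        for l in group:
            if cur and l.span_start < max(x.span_end for x in cur):
                cur.append(l)
            else:
                if cur:
                    regions.append(_region_of(cid, strand, cur))
                cur = [l]
        if cur:
            regions.append(_region_of(cid, strand, cur))
    regions.sort(key=lambda r: (r.contig_id, r.start, r.end, r.strand))
    return regions


def _region_of(cid: str, strand: str, group: list[CandidateLocus]) -> MatchedRegion:
    return MatchedRegion(
        contig_id=cid, strand=strand,
        start=min(l.span_start for l in group),
        end=max(l.span_end for l in group),
        query_ids=sorted({l.query_id for l in group}),
        best_identity=max(l.best_identity for l in group),
    )
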