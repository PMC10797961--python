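"""Hit chaining, full-length selection, matched-region merging."""

from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxannot.alignment import LocalHit
from toxannot.loci import (FullLengthRule, build_matched_regions, chain_hits,
                           classify_locus)

JOIN = 10.0
GAP_PER_KB = 1.0


def H(qs, qe, ts, te, score=None, strand="+", query="q", contig="c", ident=0.95):
    return LocalHit(query, contig, strand, qs, qe, ts, te, ident,
                    float(score if score is not None else 2 * (qe - qs)))


def oracle_best_chain_score(hits, max_gene_size):
    """Exhaustive best collinear subset, independent re-statement of the
    chain objective (sum of scores - join penalty - 1/kb genomic gap)."""

    def compatible(a, b, strand):
        if b.qstart < a.qstart or b.qend <= a.qend:
            return False
        qov = a.qend - b.qstart
        if qov > 15:
            return False
        allow = max(0, qov)
        if strand == "+":
            return b.tstart >= a.tend - allow and b.tend > a.tend
        return b.tend <= a.tstart + allow and b.tstart < a.tstart

    best = 0.0
    for r in range(1, len(hits) + 1):
        for combo in combinations(range(len(hits)), r):
            chain = sorted((hits[i] for i in combo), key=lambda h: h.qstart)
            strand = chain[0].strand
            if any(h.strand != strand for h in chain):
                continue
            if any(not compatible(a, b, strand) for a, b in zip(chain, chain[1:])):
                continue
            lo = min(h.tstart for h in chain)
            hi = max(h.tend for h in chain)
            if hi - lo > max_gene_size:
                continue
            score = sum(h.score for h in chain)
            for a, b in zip(chain, chain[1:]):
                gap = (b.tstart - a.tend) if strand == "+" else (a.tstart - b.tend)
                score -= JOIN + GAP_PER_KB * max(0, gap) / 1000.0
            best = max(best, score)
    return best


def test_three_collinear_exon_hits_form_one_locus():
    hits = [H(0, 100, 1000, 1100), H(100, 200, 2500, 2600), H(200, 300, 4900, 5000)]
    loci = chain_hits(hits, 50_000, {"q": 300})
    assert len(loci) == 1
    assert len(loci[0].hits) == 3
    assert (loci[0].span_start, loci[0].span_end) == (1000, 5000)
    assert loci[0].query_coverage == pytest.approx(1.0)


def test_span_bound_splits_distant_hit_groups():
    """Hit groups 80 kb apart never share a locus under the 50-kb gene size."""
    hits = [H(0, 150, 1000, 1150), H(150, 300, 81_000, 81_150)]
    loci = chain_hits(hits, 50_000, {"q": 300})
    assert len(loci) == 2
    wide = chain_hits(hits, 100_000, {"q": 300})
    assert len(wide) == 1  # raising the bound can only merge


def test_opposite_strand_hits_never_chain():
    hits = [H(0, 150, 1000, 1150, strand="+"), H(150, 300, 2000, 2150, strand="-")]
    loci = chain_hits(hits, 50_000, {"q": 300})
    assert len(loci) == 2
    assert all(len(l.hits) == 1 for l in loci)


def test_target_order_never_contradicts_query_order():
    # second hit earlier on the genome: collinearity forbids chaining on "+"
    hits = sorted([H(0, 150, 5000, 5150), H(150, 300, 1000, 1150)],
                  key=lambda h: h.tstart)
    loci = chain_hits(hits, 50_000, {"q": 300})
    assert all(len(l.hits) == 1 for l in loci)


def test_minus_strand_chain_runs_against_forward_coordinates():
    hits = [H(0, 150, 5000, 5150, strand="-"), H(150, 300, 1000, 1150, strand="-")]
    loci = chain_hits(hits, 50_000, {"q": 300})
    assert len(loci) == 1
    assert [h.qstart for h in loci[0].hits] == [0, 150]
    assert (loci[0].span_start, loci[0].span_end) == (1000, 5150)


@pytest.mark.parametrize("case", range(8))
def test_chain_score_equals_bruteforce_oracle(case):
    """On <= 8 hits the DP chain score equals exhaustive subset enumeration."""
    import numpy as np

    rng = np.random.default_rng(100 + case)
    n = int(rng.integers(3, 9))
    hits = []
    qpos, tpos = 0, 0
    strand = "+" if case % 2 == 0 else "-"
    raw = []
    for _ in range(n):
        qlen = int(rng.integers(30, 200))
        qs = int(rng.integers(0, 600))
        ts = int(rng.integers(0, 60_000))
        raw.append((qs, qs + qlen, ts, ts + qlen + int(rng.integers(-10, 10))))
    for qs, qe, ts, te in raw:
        if te <= ts:
            te = ts + (qe - qs)
        hits.append(H(qs, qe, ts, te, score=float(qe - qs), strand=strand))
    hits.sort(key=lambda h: h.tstart)
    loci = chain_hits(hits, 50_000, {"q": 800})
    assert max(l.score for l in loci) == pytest.approx(
        oracle_best_chain_score(hits, 50_000))


@given(st.lists(st.tuples(st.integers(0, 500), st.integers(20, 150),
                          st.integers(0, 40_000), st.integers(-8, 8)),
                min_size=1, max_size=6),
       st.sampled_from(["+", "-"]))
def test_chain_score_equals_oracle_on_generated_hits(raw, strand):
    """Property form of the chaining oracle on arbitrary small hit sets."""
    hits = []
    for qs, qlen, ts, skew in raw:
        tlen = max(1, qlen + skew)
        hits.append(H(qs, qs + qlen, ts, ts + tlen, score=float(qlen),
                      strand=strand))
    hits.sort(key=lambda h: h.tstart)
    loci = chain_hits(hits, 50_000, {"q": 800})
    assert max(l.score for l in loci) == pytest.approx(
        oracle_best_chain_score(hits, 50_000))
    # partition: every hit lands in exactly one locus
    assert sum(len(l.hits) for l in loci) == len(hits)


def test_max_gene_size_monotonicity():
    hits = [H(0, 100, 1000, 1100), H(100, 200, 30_000, 30_100),
            H(200, 300, 70_000, 70_100)]
    small = chain_hits(hits, 40_000, {"q": 300})
    large = chain_hits(hits, 80_000, {"q": 300})
    assert max(len(l.hits) for l in large) >= max(len(l.hits) for l in small)


def test_full_length_classification_rules():
    rule = FullLengthRule()  # coverage 0.95, end tolerance 10
    full = chain_hits([H(0, 300, 1000, 1300)], 50_000, {"q": 300})[0]
    assert classify_locus(full, 300, rule) == "full_length"
    partial = chain_hits([H(0, 210, 1000, 1210)], 50_000, {"q": 300})[0]
    assert classify_locus(partial, 300, rule) == "partial"  # 70% coverage
    # 96% coverage but missing the start beyond the 10-bp terminus tolerance
    offset = chain_hits([H(40, 330, 1000, 1290)], 50_000, {"q": 330})[0]
    assert classify_locus(offset, 330, rule) == "partial"


def test_matched_regions_merge_overlaps_and_keep_order():
    l1 = chain_hits([H(0, 300, 1000, 4000, query="q1")], 50_000, {"q1": 300})[0]
    l2 = chain_hits([H(0, 300, 3000, 6000, query="q2")], 50_000, {"q2": 300})[0]
    l3 = chain_hits([H(0, 300, 9000, 9300, query="q1")], 50_000, {"q1": 300})[0]
    regions = build_matched_regions([l1, l2, l3])
    assert [(r.start, r.end) for r in regions] == [(1000, 6000), (9000, 9300)]
    assert regions[0].query_ids == ["q1", "q2"]
    assert build_matched_regions([]) == []


def test_matched_regions_are_strand_specific():
    """Overlapping opposite-strand loci stay separate (inverted gene pairs)."""
    plus = chain_hits([H(0, 300, 1000, 4000, strand="+")], 50_000, {"q": 300})[0]
    minus = chain_hits([H(0, 300, 2000, 5000, strand="-")], 50_000, {"q": 300})[0]
    regions = build_matched_regions([plus, minus])
    assert len(regions) == 2
    assert {r.strand for r in regions} == {"+", "-"}
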