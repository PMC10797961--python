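"""Seed index, local hit search, pairwise identity, tabular adapter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxannot.alignment import (GenomeAssembly, SearchParams, SeedIndex,
                                pairwise_identity, read_hits_tsv, revcomp,
                                search_hits, write_hits_tsv)
from toxannot.simulate import generate_background, mutate_cds, random_cds
from toxannot.toxindb import ToxinDatabase, ToxinRecord


def smith_waterman_score(a: str, b: str, match=2, mismatch=-3, gap_open=-5,
                         gap_extend=-2) -> float:
    """Quadratic-time affine-gap local alignment score (independent oracle)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _db(cds, rec_id="q|FAM"):
    return ToxinDatabase([ToxinRecord(rec_id, "FAM", cds)])


def test_seed_index_positions_and_n_exclusion():
    idx = SeedIndex(GenomeAssembly({"c": "ACGTACGT"}), k=4)
    hits = idx.lookup("ACGT")
    assert [(c, p) for c, p, s in hits if s == "+"] == [("c", 0), ("c", 4)]
    idx_n = SeedIndex(GenomeAssembly({"c": "ACGNACGT"}), k=4)
    assert [(c, p) for c, p, s in idx_n.lookup("ACGN")] == []
    assert [(c, p) for c, p, s in idx_n.lookup("ACGT") if s == "+"] == [("c", 4)]


def test_seed_index_strand_mirror_under_reverse_complement():
    genome = generate_background(200, 0.5, seed=3)
    k = 6
    idx = SeedIndex(GenomeAssembly({"c": genome}), k=k)
    idx_rc = SeedIndex(GenomeAssembly({"c": revcomp(genome)}), k=k)
    kmer = genome[50:56]
    fwd = {(p, s) for _, p, s in idx.lookup(kmer)}
    mirrored = {(len(genome) - k - p, "+-"["+-".index(s) - 1]) for _, p, s in idx_rc.lookup(kmer)}
    assert fwd == mirrored


def test_empty_genome_rejected():
    with pytest.raises(ValueError):
        SeedIndex(GenomeAssembly({}), k=11)


@pytest.mark.parametrize(
    "a, b, expected",
    [("ACGTACGT", "ACGTACGT", 1.0), ("AAAA", "AAAT", 0.75)],
)
def test_pairwise_identity_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)
    assert pairwise_identity(b, a) == pytest.approx(expected)


def test_pairwise_identity_substitution_oracle():
    a = random_cds(100, seed=4)  # 300 nt
    b = mutate_cds(a, 0.99, seed=5)  # 3 substitutions
    n_diff = sum(x != y for x, y in zip(a, b))
    assert n_diff == 3
    assert pairwise_identity(a, b) == pytest.approx(297 / 300)


dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


@given(dna, dna)
def test_pairwise_identity_symmetric_and_bounded(a, b):
    ab, ba = pairwise_identity(a, b), pairwise_identity(b, a)
    assert ab == pytest.approx(ba)
    assert 0.0 <= ab <= 1.0
    assert pairwise_identity(a, a) == 1.0


def test_exact_insert_found_with_full_coordinates():
    cds = random_cds(100, seed=6)  # 300 nt
    bg = generate_background(5000, 0.4, seed=7)
    genome = GenomeAssembly({"c": bg[:1000] + cds + bg[1000:]})
    hits = search_hits(_db(cds), genome, SearchParams())
    assert len(hits) == 1
    h = hits[0]
    assert (h.strand, h.qstart, h.qend, h.tstart, h.tend) == ("+", 0, 300, 1000, 1300)
    assert h.identity == 1.0


def test_reverse_complement_insert_found_on_minus_strand():
    cds = random_cds(100, seed=6)
    bg = generate_background(5000, 0.4, seed=7)
    genome = GenomeAssembly({"c": bg[:1000] + revcomp(cds) + bg[1000:]})
    hits = search_hits(_db(cds), genome, SearchParams())
    assert len(hits) == 1
    h = hits[0]
    assert (h.strand, h.tstart, h.tend, h.qstart, h.qend) == ("-", 1000, 1300, 0, 300)
    # coordinate round-trip: the reverse-complemented target equals the query
    assert revcomp(genome.contigs["c"][h.tstart:h.tend]) == cds


def test_random_query_vs_background_yields_no_hits():
    cds = random_cds(100, seed=8)
    genome = GenomeAssembly({"c": generate_background(100_000, 0.4, seed=9)})
    hits = search_hits(_db(cds), genome, SearchParams())
    assert hits == []
    # oracle: the best local score in a window is below the reporting threshold
    window = genome.contigs["c"][:2000]
    assert smith_waterman_score(window, cds) < SearchParams().min_score


def test_engine_score_matches_quadratic_oracle_on_window():
    cds = random_cds(80, seed=10)  # 240 nt
    # substitutions confined to the interior: the local-alignment optimum then
    # ends on exact-match runs, which the engine's end-anchoring preserves
    diverged = list(cds)
    for pos in range(60, 180, 37):
        diverged[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[diverged[pos]]
    diverged = "".join(diverged)
    bg = generate_background(2000, 0.4, seed=12)
    window = bg[:800] + diverged + bg[800:]
    genome = GenomeAssembly({"w": window})
    hits = search_hits(_db(cds), genome, SearchParams())
    assert len(hits) == 1
    assert hits[0].score == pytest.approx(smith_waterman_score(window, cds))


def test_strand_symmetry_of_search():
    cds = random_cds(90, seed=13)
    bg = generate_background(8000, 0.4, seed=14)
    seq = bg[:2000] + cds + bg[2000:5000] + revcomp(cds) + bg[5000:]
    genome = GenomeAssembly({"c": seq})
    mirrored = GenomeAssembly({"c": revcomp(seq)})
    hits = search_hits(_db(cds), genome, SearchParams())
    hits_rc = search_hits(_db(cds), mirrored, SearchParams())
    n = len(seq)
    flipped = sorted((h.query_id, "+-"["+-".index(h.strand) - 1], h.qstart, h.qend,
                      n - h.tend, n - h.tstart, round(h.identity, 6), h.score)
                     for h in hits_rc)
    direct = sorted((h.query_id, h.strand, h.qstart, h.qend, h.tstart, h.tend,
                     round(h.identity, 6), h.score) for h in hits)
    assert direct == flipped


def test_hits_tsv_round_trip(tmp_path):
    cds = random_cds(100, seed=15)
    bg = generate_background(4000, 0.4, seed=16)
    genome = GenomeAssembly({"c": bg[:500] + cds + bg[500:2000] + revcomp(cds) + bg[2000:]})
    hits = search_hits(_db(cds), genome, SearchParams())
    assert {h.strand for h in hits} == {"+", "-"}
    path = tmp_path / "hits.tsv"
    write_hits_tsv(hits, path)
    back = read_hits_tsv(path)
    assert [(h.query_id, h.contig_id, h.strand, h.qstart, h.qend, h.tstart, h.tend)
            for h in back] == [(h.query_id, h.contig_id, h.strand, h.qstart, h.qend,
                                h.tstart, h.tend) for h in hits]
    # minus strand is encoded as sstart > send in the file
    for line in path.read_text().splitlines():
        f = line.split("\t")
        if int(f[8]) > int(f[9]):
            assert any(h.strand == "-" and h.tstart == int(f[9]) - 1 for h in hits)
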