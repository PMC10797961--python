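"""Gene-model finalization, classification, dedup, translation, GTF round trip."""

import pytest

from toxannot.alignment import GenomeAssembly, revcomp
from toxannot.gtf import (read_annotation_models, spliced_cds_from_gtf,
                          write_annotation_gtf)
from toxannot.loci import CandidateLocus
from toxannot.models import (GeneModel, classify_annotation, extract_region,
                             finalize_model, resolve_overlaps, translate)
from toxannot.simulate import generate_background, generate_toxin_gene, random_cds
from toxannot.spliced import spliced_align
from toxannot.toxindb import ToxinRecord


def _locus(contig, strand, start, end, query="q|FAM"):
    from toxannot.alignment import LocalHit
    hit = LocalHit(query, contig, strand, 0, 10, start, end, 1.0, 20.0)
    return CandidateLocus(query_id=query, contig_id=contig, strand=strand,
                          hits=[hit], span_start=start, span_end=end,
                          query_coverage=1.0, score=20.0, status="full_length")


@pytest.mark.parametrize("s, e, flank, expect", [
    (10_000, 12_000, 500, (9_500, 12_500)),
    (200, 1_000, 500, (0, 1_500)),  # clipped at the contig start
])
def test_extract_region_window_and_clipping(s, e, flank, expect):
    genome = GenomeAssembly({"c": generate_background(20_000, 0.4, 50)})
    region, mapping = extract_region(genome, _locus("c", "+", s, e), flank)
    assert (mapping.g_start, mapping.g_end) == expect
    assert region == genome.contigs["c"][expect[0]:expect[1]]


def test_extract_region_minus_strand_round_trips():
    genome = GenomeAssembly({"c": generate_background(5_000, 0.4, 51)})
    region, mapping = extract_region(genome, _locus("c", "-", 1_000, 2_000), 100)
    contig = genome.contigs["c"]
    for r in (0, 1, 57, len(region) - 1):
        g = mapping.position(r)
        assert revcomp(contig[g]) == region[r]


def _finalized(cds, gene_seq, strand="+", flank=200, **kw):
    bg_l = generate_background(flank, 0.4, 60)
    bg_r = generate_background(flank, 0.4, 61)
    contig = bg_l + (gene_seq if strand == "+" else revcomp(gene_seq)) + bg_r
    genome = GenomeAssembly({"c": contig})
    locus = _locus("c", strand, flank, flank + len(gene_seq))
    region, mapping = extract_region(genome, locus, flank)
    aln = spliced_align(cds, region)
    rec = ToxinRecord("q|FAM", "FAM", cds)
    return genome, finalize_model(aln, rec, mapping, region, min_cds_len=60, **kw)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_clean_gene_round_trips_to_exact_cds(strand):
    cds = random_cds(80, seed=62)
    layout = generate_toxin_gene(cds, [300, 90], seed=63)
    genome, model = _finalized(cds, layout.sequence, strand=strand)
    assert isinstance(model, GeneModel)
    assert model.cds == cds
    assert model.status == "reliable"
    assert model.strand == strand
    assert len(model.exons) == 3
    assert model.phases[0] == 0
    # phases follow cumulative CDS length
    cum = 0
    for (s, e), phase in zip(model.exons, model.phases):
        assert phase == (3 - cum % 3) % 3
        cum += e - s


def test_start_rescue_recovers_upstream_atg():
    """Alignment starting two codons into the CDS is rescued to the true ATG."""
    cds = random_cds(80, seed=64)
    genome, model = _finalized(cds[6:], cds, rescue_codons=30)
    assert isinstance(model, GeneModel)
    assert model.cds == cds  # extended back to the implanted start


def test_rejection_when_no_stop_in_rescue_window():
    cds = random_cds(80, seed=65)
    # remove the terminal stop and surround with stop-free sequence
    gene = cds[:-3] + "GGG" * 40
    genome, model = _finalized(cds, gene, rescue_codons=3)
    from toxannot.models import ModelRejection
    if isinstance(model, ModelRejection):
        assert model.reason in {"no_stop_codon", "no_start_codon"}
    else:
        # if a chance in-frame stop existed nearby, the model must be canonical
        assert model.cds[-3:] in {"TAA", "TAG", "TGA"}


def test_translate_examples():
    assert translate("ATGAAATAG") == "MK"
    assert translate("ATGTGAAAATAG") == "M*K"
    with pytest.raises(ValueError):
        translate("ATGAA")
    cds = random_cds(50, seed=66)
    assert len(translate(cds)) == len(cds) // 3 - 1


def _mk(score, ident, exons, query="qa", contig="c", strand="+", cds_len=300):
    cds = "ATG" + "A" * (cds_len - 6) + "TAA"
    return GeneModel(id="", contig_id=contig, strand=strand, exons=exons,
                     phases=[0] * len(exons), cds=cds, peptide="",
                     status="reliable", source_query=query, family="F",
                     score=score, identity=ident)


def test_resolve_overlaps_keeps_best_and_is_order_invariant():
    a = _mk(500, 0.97, [(1000, 1300)], query="qa")
    b = _mk(450, 0.99, [(1050, 1350)], query="qb")
    c = _mk(450, 0.92, [(1100, 1400)], query="qc")
    d = _mk(400, 0.90, [(9000, 9300)], query="qd")
    kept = resolve_overlaps([a, b, c, d])
    assert [m.source_query for m in kept] == ["qa", "qd"]
    for perm in ([d, c, b, a], [b, d, a, c]):
        assert [m.source_query for m in resolve_overlaps(perm)] == ["qa", "qd"]


def test_resolve_overlaps_ties_broken_by_identity():
    a = _mk(450, 0.97, [(1000, 1300)], query="qa")
    b = _mk(450, 0.92, [(1000, 1300)], query="qb")
    assert [m.source_query for m in resolve_overlaps([a, b])] == ["qa"]


def test_resolve_overlaps_disjoint_and_opposite_strand_kept():
    a = _mk(500, 0.97, [(1000, 1300)], query="qa", strand="+")
    b = _mk(400, 0.97, [(1100, 1400)], query="qb", strand="-")
    c = _mk(300, 0.97, [(5000, 5300)], query="qc", strand="+")
    assert len(resolve_overlaps([a, b, c])) == 3


def test_classify_annotation_is_frame_aware():
    reliable = _mk(10, 1.0, [(0, 300)])
    assert classify_annotation(reliable) == "reliable"
    # TGA appears out of frame only: AT-GTG-A.. pattern
    cds = "ATG" + "GTGAAA" * 20 + "AAA" * 5 + "TAA"
    m = _mk(10, 1.0, [(0, len(cds))])
    m.cds = cds
    assert "TGA" in cds and classify_annotation(m) == "reliable"
    m.cds = "ATG" + "TGA" + "AAA" * 30 + "TAA"
    assert classify_annotation(m) == "warning"


def test_gtf_round_trip_reproduces_cds_bytes(small_run, tmp_path):
    genome, truth, result = small_run
    path = tmp_path / "ann.gtf"
    write_annotation_gtf(result.models, path)
    parsed = read_annotation_models(path)
    assert set(parsed) == {m.id for m in result.models}
    for m in result.models:
        assert spliced_cds_from_gtf(genome, parsed[m.id]) == m.cds
        assert parsed[m.id]["attributes"]["status"] == m.status


def test_best_match_report_identifies_source_protein(small_run):
    genome, truth, result = small_run
    from toxannot.models import best_match_report
    proteins = {f"ref_{g.gene_id}": translate(g.source_cds) for g in truth.genes
                if not g.is_pseudogene}
    rows = best_match_report([m for m in result.models if m.status == "reliable"],
                             proteins)
    assert rows
    for row in rows:
        assert row["subject"] != "NA"
        assert row["identity"] == pytest.approx(1.0)
        assert row["coverage"] == pytest.approx(1.0)


def test_emitted_introns_are_canonical(small_run):
    genome, truth, result = small_run
    for m in result.models:
        contig = genome.contigs[m.contig_id]
        exons = sorted(m.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            intron = contig[e1:s2]
            if m.strand == "-":
                intron = revcomp(intron)
            assert intron[:2] == "GT" and intron[-2:] == "AG"
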