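"""Deterministic synthetic genomes with implanted toxin genes and truth.

The generator emulates the structures the annotator must handle: i.i.d.
background sequence at a chosen GC, multi-exon toxin genes with canonical
GT..AG introns, diverged paralogs (substitution-only), and pseudogenes
carrying one premature in-frame stop. Every output is a deterministic
function of (parameters, seed), and the machine-readable truth round-trips
through the same GTF dialect the pipeline emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import GenomeAssembly, revcomp
from .models import GeneModel, translate
from .toxindb import STOP_CODONS, ToxinDatabase, ToxinRecord

BASES = np.array(list("ACGT"))
_STOPS = sorted(STOP_CODONS)

DEFAULT_FAMILIES = ("SVMP", "SVSP", "PLA2", "CTL", "LAO")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_background(length: int, gc: float = 0.40, seed=0) -> str:
    """i.i.d. nucleotide sequence with expected GC content ``gc``."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def random_cds(n_codons: int, seed=0) -> str:
    """A valid CDS: ATG, ``n_codons - 2`` random non-stop codons, one stop."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons")
    rng = _rng(seed)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def mutate_cds(cds: str, target_identity: float, seed=0,
               pseudogenize: bool = False) -> str:
    """Substitution-only divergence preserving full-length CDS validity.

    Substitutions avoid the start codon, the terminal stop, and never
    create an in-frame stop; realized identity is 1 - n_sub/len (within
    0.02 of target). With ``pseudogenize``, exactly one interior codon is
    rewritten to a stop afterwards.
    """
    if not 0.5 <= target_identity <= 1:
        raise ValueError("target_identity must be in [0.5, 1]")
    rng = _rng(seed)
    seq = list(cds)
    n = len(cds)
    n_sub = round((1 - target_identity) * n)
    positions = rng.choice(np.arange(3, n - 3), size=min(n_sub, n - 6), replace=False)
    for pos in sorted(int(p) for p in positions):
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for b in choices:
            seq[pos] = b
            c0 = pos - pos % 3
            if "".join(seq[c0 : c0 + 3]) not in STOP_CODONS:
                break
            seq[pos] = old
    if pseudogenize:
        codon_idx = int(rng.integers(1, n // 3 - 1))
        stop = _STOPS[rng.integers(len(_STOPS))]
        seq[codon_idx * 3 : codon_idx * 3 + 3] = list(stop)
    return "".join(seq)


@dataclass
class GeneLayout:
    """A gene in transcription orientation: exon intervals in gene coordinates."""

    sequence: str
    exons: list[tuple[int, int]]
    cds: str


def generate_toxin_gene(cds: str, intron_lengths: list[int], seed=0,
                        min_exon: int = 30) -> GeneLayout:
    """Interleave the CDS with canonical GT..AG introns at random split points.

    Split points need not respect codon boundaries but keep every exon at
    least ``min_exon`` bp (real coding exons below ~30 bp are vanishingly
    rare, and micro-exons would be undetectable by any similarity search).
    """
    rng = _rng(seed)
    for L in intron_lengths:
        if L < 4:
            raise ValueError("intron shorter than 4 cannot hold GT..AG")
    n_introns = len(intron_lengths)
    if n_introns == 0:
        return GeneLayout(sequence=cds, exons=[(0, len(cds))], cds=cds)
    if (n_introns + 1) * min_exon > len(cds):
        raise ValueError("too many introns for CDS length")
    lo, hi = min_exon, len(cds) - min_exon
    for _ in range(500):
        splits = sorted(int(s) for s in
                        rng.choice(np.arange(lo, hi + 1), size=n_introns, replace=False))
        if all(b - a >= min_exon for a, b in zip(splits, splits[1:])):
            break
    else:  # deterministic fallback: evenly spaced splits
        step = len(cds) // (n_introns + 1)
        splits = [step * (i + 1) for i in range(n_introns)]
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    prev = 0
    offset = 0
    for split, ilen in zip(splits, intron_lengths):
        exon = cds[prev:split]
        parts.append(exon)
        exons.append((offset, offset + len(exon)))
        offset += len(exon)
        interior = "".join(rng.choice(BASES, size=ilen - 4))
        parts.append("GT" + interior + "AG")
        offset += ilen
        prev = split
    parts.append(cds[prev:])
    exons.append((offset, offset + len(cds) - prev))
    return GeneLayout(sequence="".join(parts), exons=exons, cds=cds)


@dataclass
class ImplantedGene:
    gene_id: str
    family: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, transcription order
    cds: str  # implanted CDS (may carry a premature stop)
    source_cds: str  # the clean CDS the gene was derived from
    is_pseudogene: bool


@dataclass
class FixtureTruth:
    genes: list[ImplantedGene]
    seed: int
    parameters: dict = field(default_factory=dict)

    def to_models(self) -> list[GeneModel]:
        """Truth as gene models (for GTF emission in the pipeline dialect)."""
        models = []
        for g in self.genes:
            phases, cum = [], 0
            for s, e in g.exons:
                phases.append((3 - cum % 3) % 3)
                cum += e - s
            models.append(GeneModel(
                id=g.gene_id, contig_id=g.contig_id, strand=g.strand,
                exons=list(g.exons), phases=phases, cds=g.cds,
                peptide=translate(g.cds),
                status="warning" if g.is_pseudogene else "reliable",
                source_query=g.gene_id, family=g.family, score=0.0, identity=1.0,
            ))
        return models

    def database(self) -> ToxinDatabase:
        """Database of the (clean) source CDSs of all implanted genes."""
        seen: set[str] = set()
        records = []
        for g in self.genes:
            if g.source_cds in seen:
                continue
            seen.add(g.source_cds)
            records.append(ToxinRecord(id=f"{g.gene_id}|{g.family}",
                                       family=g.family, cds=g.source_cds))
        return ToxinDatabase(records=records, source="fixture-truth")


def implant(background: dict[str, str], genes: list[GeneLayout],
            placements: list[tuple[str, int, str]], gene_meta: list[dict],
            seed: int = 0) -> tuple[GenomeAssembly, FixtureTruth]:
    """Splice genes into background contigs (replacement, not insertion).

    ``placements``: (contig_id, start, strand) per gene; implant intervals
    must be pairwise disjoint and inside their contig. For strand ``-`` the
    genome carries the reverse complement; truth exons stay in
    transcription order.
    """
    contigs = {cid: list(seq) for cid, seq in background.items()}
    intervals: dict[str, list[tuple[int, int]]] = {}
    truth_genes: list[ImplantedGene] = []
    for layout, (cid, start, strand), meta in zip(genes, placements, gene_meta):
        glen = len(layout.sequence)
        end = start + glen
        if cid not in contigs or start < 0 or end > len(contigs[cid]):
            raise ValueError(f"implant outside contig {cid}")
        for s, e in intervals.get(cid, []):
            if max(s, start) < min(e, end):
                raise ValueError("overlapping implants")
        intervals.setdefault(cid, []).append((start, end))
        seq = layout.sequence if strand == "+" else revcomp(layout.sequence)
        contigs[cid][start:end] = list(seq)
        if strand == "+":
            g_exons = [(start + s, start + e) for s, e in layout.exons]
        else:
            g_exons = [(end - e, end - s) for s, e in layout.exons]
        truth_genes.append(ImplantedGene(
            gene_id=meta["gene_id"], family=meta["family"], contig_id=cid,
            strand=strand, exons=g_exons, cds=layout.cds,
            source_cds=meta.get("source_cds", layout.cds),
            is_pseudogene=meta.get("is_pseudogene", False),
        ))
    genome = GenomeAssembly(contigs={c: "".join(s) for c, s in contigs.items()})
    return genome, FixtureTruth(genes=truth_genes, seed=seed)


def make_boundary_fixture(seed: int = 0) -> tuple[GenomeAssembly, FixtureTruth]:
    """Two genes that straddle the default size thresholds.

    One 900-nt CDS whose single 51.2-kb intron inflates the gene span to
    ~52 kb (beyond the 50-kb default maximum gene size), and one 195-nt
    CDS (the longest codon-multiple length below the 200-bp default CDS
    minimum). Neither is annotatable under defaults; both are recovered
    with a 100-kb gene size and a 150-bp CDS minimum.
    """
    rng = np.random.default_rng(seed)
    background = {"ctg_big": generate_background(60_000, 0.40, rng),
                  "ctg_small": generate_background(20_000, 0.40, rng)}
    big_cds = random_cds(300, rng)  # 900 nt
    big = generate_toxin_gene(big_cds, [51_200], rng)
    small_cds = random_cds(65, rng)  # 195 nt
    small = generate_toxin_gene(small_cds, [400], rng)
    genome, truth = implant(
        background, [big, small],
        [("ctg_big", 3000, "+"), ("ctg_small", 5000, "-")],
        [{"gene_id": "ENPP_like_g1", "family": "ENPP"},
         {"gene_id": "MYO_like_g2", "family": "MYO"}],
        seed=seed)
    truth.parameters = {"big_span": len(big.sequence), "small_cds_len": len(small_cds)}
    return genome, truth


def make_fixture(seed: int = 0, genome_length: int = 1_000_000, n_contigs: int = 5,
                 n_genes: int = 20, families: tuple[str, ...] = DEFAULT_FAMILIES,
                 max_exons: int = 8, intron_range: tuple[int, int] = (60, 3000),
                 cds_codon_range: tuple[int, int] = (100, 400), gc: float = 0.40,
                 n_pseudogenes: int = 0,
                 paralog_identity: float | None = None) -> tuple[GenomeAssembly, FixtureTruth]:
    """Default study fixture: a 1-Mb genome carrying 20 multi-exon toxin genes.

    Genes are spread over ``n_contigs`` contigs on both strands with 1-8
    exons and 60-3000 bp introns. The last ``n_pseudogenes`` genes carry a
    premature stop. With ``paralog_identity`` set, implanted genes are
    diverged copies of per-family founder CDSs (the founders, not the
    implants, populate ``truth.database()``).
    """
    rng = np.random.default_rng(seed)
    contig_len = genome_length // n_contigs
    background = {f"contig_{i + 1}": generate_background(contig_len, gc, rng)
                  for i in range(n_contigs)}

    founders = {fam: random_cds(int(rng.integers(*cds_codon_range)), rng)
                for fam in families}
    layouts, placements, metas = [], [], []
    margin = 2000
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in background}
    for i in range(n_genes):
        fam = families[i % len(families)]
        is_pseudo = i >= n_genes - n_pseudogenes
        clean = founders[fam]
        if paralog_identity is not None and paralog_identity < 1.0:
            implant_cds = mutate_cds(clean, paralog_identity, rng, pseudogenize=is_pseudo)
        elif is_pseudo:
            implant_cds = mutate_cds(clean, 1.0, rng, pseudogenize=True)
        else:
            implant_cds = clean
        n_introns = min(int(rng.integers(0, max_exons)), len(implant_cds) // 30 - 1)
        intron_lengths = [int(rng.integers(*intron_range)) for _ in range(n_introns)]
        layout = generate_toxin_gene(implant_cds, intron_lengths, rng)
        glen = len(layout.sequence)
        # deterministic rejection-sampled placement
        for _ in range(1000):
            cid = f"contig_{int(rng.integers(1, n_contigs + 1))}"
            start = int(rng.integers(margin, contig_len - margin - glen))
            if all(max(s - margin, start) >= min(e + margin, start + glen)
                   for s, e in used[cid]):
                break
        else:  # pragma: no cover - generous genome, never hit
            raise RuntimeError("could not place gene")
        used[cid].append((start, start + glen))
        strand = "+" if rng.integers(2) == 0 else "-"
        layouts.append(layout)
        placements.append((cid, start, strand))
        metas.append({"gene_id": f"{fam}_g{i + 1}", "family": fam,
                      "source_cds": clean, "is_pseudogene": is_pseudo})
    genome, truth = implant(background, layouts, placements, metas, seed=seed)
    truth.parameters = {"genome_length": genome_length, "n_genes": n_genes,
                        "n_pseudogenes": n_pseudogenes, "gc": gc,
                        "paralog_identity": paralog_identity}
    return genome, truth
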