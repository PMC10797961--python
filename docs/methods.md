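# Methods

This note documents the models, algorithms, parameters, and design
decisions behind `toxannot`, and what the synthetic test bed does and does
not demonstrate.

## Problem setting and assumptions

The package annotates toxin genes in genome assemblies of venomous
lineages by similarity to a database of full-length toxin coding
sequences. A *full-length CDS* is defined throughout as: canonical ATG
start, canonical terminal stop (TAA/TAG/TGA), codon-multiple length, no
internal in-frame stop, and length at least the configured minimum
(default 200 bp). Gene models accept only canonical GT..AG splice sites.
These are deliberate restrictions: genes with non-canonical starts, stops
or splice sites, and partial genes on fragmented contigs, are out of
scope and will not be annotated (their loci may still appear in the
matched-regions output).

## Database handling

Input FASTA records are validated against the full-length definition;
invalid records are dropped with a logged warning rather than aborting,
because public sequence sets are noisy. The family label is taken from
the header token after the last `|`, else from the id with a trailing
copy-number suffix removed.

Redundancy reduction uses greedy longest-first clustering at a default
identity of 0.99: records sorted by decreasing length (ties by id) join
the first cluster whose representative they match at or above the
threshold, else found a new cluster; representatives are the founders.
Identity between two sequences is the fraction of matching columns in an
optimal global (Needleman–Wunsch) alignment — match +1, mismatch −1, gap
open −2, extend −1 — with *every* column counted, so length differences
reduce identity. An end-free variant was rejected: with free terminal
gaps, a single trailing substitution can be shifted into an overhang and
scored as identity 1.0, which contradicts the intended meaning
(`AAAA` vs `AAAT` must be 0.75).

Merging a main and a custom database removes exact duplicate sequences
(first occurrence wins) and renames id collisions deterministically by
suffixing.

## Similarity search

The search engine is an internal seed-and-extend design with a tabular
adapter, so an external aligner can be substituted bit-compatibly through
BLAST outfmt-6 files.

* **Index**: exact *k*-mer index (default *k* = 11) per contig, built as
  a sorted integer-code array (2-bit encoding; windows containing N are
  excluded). Minus-strand lookups query the reverse complement of the
  seed, so both strands are served by one forward index.
* **Banding**: seed matches are grouped by alignment diagonal (drift
  ≤ 20 bp, seed gap ≤ 150 bp, at least 2 seeds). One band corresponds to
  one putative exon hit; introns shift the diagonal by their length and
  therefore start new bands.
* **Extension**: each band is extended by a gapped local alignment
  (match +2, mismatch −3, gap open −5, extend −2) over the seed extent
  plus a 12-bp pad on each side. Hits are trimmed so that they begin and
  end with 8 consecutive exact matches. Both numbers are load-bearing:
  local extension happily crosses a true exon boundary on a weakly
  positive mismatch-rich tail, and untrimmed overshoot larger than the
  15-bp chaining overlap allowance (below) disconnects exon chains. The
  pad bounds single-sided overshoot below that allowance; the anchor
  removes mismatch-rich tails deterministically.
* **Filters**: hits below identity 0.80 or score 50 are dropped. E-values
  are not computed; identity and score are the user-facing knobs.

## Locus chaining and selection

Hits of one (query, contig, strand) group are chained by an exact sparse
dynamic program. A chain is collinear (query intervals and genomic
intervals strictly increasing in transcription order), tolerates ≤ 15 bp
of query overlap between consecutive hits (with a matching genomic
allowance), and must span ≤ `max_gene_size` (default 50 kb) on the
genome. The objective is the sum of hit scores minus a per-join cost of
10 score units plus 1 unit per kb of genomic gap at the join. The gap
term is essential in tandem arrays: with a flat join cost, a chain can
legally skip from one array copy into the next within the span bound and
produce a chimeric locus that destroys both copies' annotations. One
score unit per kb is negligible across real introns (≤ 3 units for a
3-kb intron) but decisive across inter-copy distances.

The span bound interacts with chain scoring globally, so the DP keeps a
Pareto front of (score, chain-start coordinate) states per hit; this
makes it exact, and the test suite checks it against exhaustive subset
enumeration on small hit groups. Loci are extracted greedily
best-chain-first; each hit belongs to at most one locus, and one query
may seed several loci on a contig (tandem arrays require it).

A locus is **full-length** when its chain covers ≥ 95 % of the query CDS
and its outermost aligned query positions come within 10 bp of both
termini. Exact 100 % coverage would be brittle under local alignment at
the termini. Full-length loci, merged per contig/strand, form the
matched-regions output; regions on opposite strands are never merged
(inverted gene pairs are real and must stay separate).

## Spliced alignment and gene models

Each full-length locus, extended by a 500-bp flank and oriented to the
transcription strand, is realigned against its query CDS with a
three-state dynamic program (match/mismatch, affine gaps open −12 /
extend −2, match +5, mismatch −4) plus an intron transition: permitted
only when the skipped region segment begins GT and ends AG and its
length lies in [50 bp, `max_gene_size`]; the intron cost is a constant
−40, independent of length within bounds. The query is aligned globally
(the full CDS must be accounted for), the region locally (free flanks).

The DP is exact and unbanded. Rows are vectorized with numpy; the intron
transition needs, per row, a windowed maximum over donor positions,
computed in linear time with a running maximum filter. All scores are
integers, so float32 storage is lossless and the traceback can resolve
choices by value. At the sizes this tool targets (CDS ≤ ~2 kb, regions
≤ ~100 kb) a full DP runs in seconds, so no heuristic banding is needed
and the production path is the same path the oracle tests exercise.

Finalization maps exon segments to genome coordinates and enforces the
coding grammar. If the aligned CDS does not begin with ATG, an in-frame
scan within ±30 codons inside the first exon (extension preferred on
ties) looks for one; the terminal stop is sought analogously at the end,
with the offset constrained so the total CDS length is a codon multiple.
Models failing the scan, or shorter than the minimum CDS length, are
rejected with a typed reason — their locus remains visible only in
matched regions, which is exactly the "matched but not annotated"
surface used in supervised curation. GTF phases are computed from
cumulative CDS length.

Overlapping models on the same strand (exon-footprint overlap > 30 % of
the shorter) compete; the winner is chosen by score, then identity, then
CDS length, then lexicographic source query id — deterministic and
invariant to input order. Final ids are per-family in genomic order
(`SVMP-1`, `SVMP-2`, ...). Models with an internal in-frame stop are
written to the annotation GTF *and* to the warning file with status
`warning`; both classes count as annotations.

## Transcript screening

Venom-gland transcripts are screened against the database with the same
search engine (transcripts standing in as the target sequences). A
transcript qualifies when some hit reaches identity ≥ 0.80 and covers
≥ 50 % of the database entry; the ORF best overlapping the hit footprint
(ties to the longer ORF) is emitted as a custom database record with the
family of the best-scoring hit (ties by identity, then id). ORF calling
reports all ATG→stop frames ≥ the minimum length on both strands, and
nested ORFs sharing a stop report only the longest. A consequence worth
knowing: when a 5'UTR contains an in-frame ATG with no intervening stop,
the reported ORF extends past the true start and the derived record
carries extra N-terminal codons. This mirrors the inherent ambiguity of
ORF-based CDS discovery and is why transcript-derived records complement
rather than replace a curated database.

## Synthetic fixtures

The generator emulates the features the annotator must handle, as
deterministic functions of (parameters, seed):

* i.i.d. background sequence at a target GC (default 0.40, typical of
  snake genome averages);
* multi-exon genes: a valid random CDS interleaved with GT..AG introns at
  random split points (not necessarily codon-aligned), introns 60–3000 bp;
  every exon is at least 30 bp — real coding exons below ~30 bp are
  vanishingly rare, and unconstrained split points would otherwise
  produce 9–20-bp micro-exons that no similarity search can detect;
* paralog divergence by substitutions only (identity realized within
  0.02 of target; substitutions never touch the start/stop or create an
  in-frame stop, so diverged records remain valid database entries);
* pseudogenes: exactly one interior codon rewritten to a stop;
* implantation by replacement into disjoint background intervals on
  either strand, with truth emitted in the same GTF dialect the pipeline
  writes.

The default study fixture is a 1-Mb genome in five contigs carrying 20
genes from five families (SVMP, SVSP, PLA2, CTL, LAO; shared per-family
founder CDSs, i.e. identical tandem paralogs at different loci with
independent intron structures), sized so the full suite runs in about a
minute. A boundary fixture implants one gene whose single 51.2-kb intron
inflates its span to ~52 kb and one 195-nt CDS gene — both invisible
under default thresholds and recovered with `--gensize 100000
--mincds 150`. (195 nt is the longest codon-multiple length below the
200-bp default; a 196-nt sequence cannot be a valid CDS.)

What passing these tests shows: exact coordinate bookkeeping across
strands and formats, exact junction recovery for canonical introns,
correct threshold behavior, and robustness of the chain/model machinery
to tandem duplication, divergence, and premature stops. What they do not
show: performance on real assemblies with repeats, orphan exons,
assembly gaps, sequencing errors, or non-canonical gene structures —
the fixtures deliberately contain none of these.

## Numerical and degenerate-input choices

* All internal coordinates are 0-based half-open on the forward strand;
  conversion to 1-based inclusive happens once, in GTF emission.
* Chain DP and spliced DP are exact; ties resolve deterministically
  (diagonal preferred over intron entry; shortest intron / shortest gap
  preferred in traceback; fixed state priority M > X > Y).
* Empty databases, unreadable inputs, and malformed FASTA raise typed
  input errors (CLI exit code 2); internal failures exit 3.
* Zero hits, empty locus sets, and empty annotation sets are valid and
  produce headers-only outputs.
* Outputs are sorted by (contig, start, id) and byte-stable: identical
  inputs and configuration give byte-identical files, and the thread
  setting never changes results.

## Known limitations

* Only canonical ATG/stop/GT..AG signals; no partial-gene annotation on
  fragmented contigs.
* Protein-space (translated) search is not implemented; highly diverged
  toxins beyond ~80 % nucleotide identity require a closer database or
  transcript evidence.
* The hit-level end-anchoring (8 exact matches) slightly shortens hits of
  diverged homologs near exon boundaries, lowering their apparent
  coverage; full-length detection of < 85 %-identity homologs is
  correspondingly conservative.
* Expression-weighted evaluation is out of scope; the evaluation module
  compares annotations and reference intervals only.
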