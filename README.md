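# toxannot

Automated toxin-gene annotation for genome assemblies of venomous lineages.

Toxin genes are among the hardest gene families to annotate: they occur as
recently duplicated tandem arrays of highly similar paralogs, accumulate
truncated copies and pseudogenes with premature stop codons, and are
routinely mangled or missed by general-purpose genome annotators.
`toxannot` approaches the problem the way a venomics curator does: search
the assembly with a database of known full-length toxin coding sequences,
keep only the genomic regions that match a complete CDS, and build an
explicit exon/intron gene model for each such locus, accepting only
canonical coding signals (ATG start, TAA/TAG/TGA stop, GT..AG introns).

## Method

For a genome *G* and a toxin database *D* of full-length CDSs:

1. **Detection** — a seed-and-extend similarity search (exact *k*-mer
   seeds, *k* = 11, gapped extension with match +2, mismatch −3, gap
   −5/−2) reports local hits of every CDS in *D* on both strands of *G*.
   Precomputed hits in BLAST tabular (outfmt 6) form can be substituted.
2. **Locus selection** — hits of one query on one contig/strand are
   chained by an exact sparse dynamic program (collinear in query and
   genome, query overlap ≤ 15 bp, genomic span ≤ 50 kb by default). A
   locus is *full-length* when the chain covers ≥ 95 % of the query CDS
   and reaches both termini within 10 bp; all full-length loci are
   written to `matched_regions.gtf`.
3. **Gene models** — each full-length locus (± 500 bp flank) is realigned
   against its query with a spliced-alignment dynamic program whose
   intron state is only enterable across a GT..AG segment of 50 bp up to
   the maximum gene size; the intron cost is length-independent. Exon
   boundaries are mapped back to the genome, the start/stop codons are
   rescued by a bounded in-frame scan when needed, and competing
   overlapping models are resolved deterministically by score.
4. **Classification** — a model whose CDS carries an internal in-frame
   stop is annotated `warning` (candidate truncated paralog or
   pseudogene); all others are `reliable`.
5. **Evaluation** — given a reference annotation, the package computes the
   per-family toxin recovery rate TRR = annotated/reported, per-gene
   labels (`matched_and_annotated`, `matched_but_not_annotated`,
   `not_matched`) and the automatic/supervised precision,
   *n*<sub>annotated</sub>/*n* and
   (*n*<sub>annotated</sub>+*n*<sub>matched only</sub>)/*n*.

A custom database can be built from assembled venom-gland transcripts:
transcripts similar to the database contribute their best-overlapping
full-length ORF, labelled with the family of the best hit. Integrating
such a transcript-derived database with the main one never reduces the
number of reliable annotations and usually increases it.

A synthetic-fixture generator (`toxannot.simulate`) produces deterministic
genomes with implanted multi-exon toxin genes, diverged paralogs, and
pseudogenes, together with machine-readable truth — the test bed for the
whole pipeline.

## Worked example

Generate a 200-kb synthetic genome with six implanted toxin genes (one a
pseudogene), annotate it with the exact implanted CDSs as database, and
evaluate against the truth annotation:

```bash
toxannot make-fixture --seed 7 -o fixture --genome-length 200000 \
    --contigs 2 --genes 6 --pseudogenes 1
toxannot annotate -g fixture/genome.fasta -d fixture/database.fasta -o annotation
toxannot evaluate -a annotation/toxin_annotation.gtf \
    -m annotation/matched_regions.gtf -r fixture/truth.gtf -o eval
```

The run log summarises every stage:

```
stage=database records=5
stage=search queries=5 hits=25
stage=chain loci=6 full_length=6
stage=matched_regions regions=6
stage=gene_models built=6 rejected=0 final=6 reliable=5 warning=1
```

All six genes are annotated; the five intact genes are `reliable` and the
implanted pseudogene is flagged:

```
$ cat annotation/annotation_warning.txt
#id     contig    interval     reason
SVMP-1  contig_1  37686-44712  premature_stop_codon
```

and the evaluation reports a perfect recovery (`eval.json`):

```json
{"automatic_precision": 1.0, "supervised_precision": 1.0,
 "trr": {"CTL": 1.0, "LAO": 1.0, "PLA2": 1.0, "SVMP": 1.0, "SVSP": 1.0}}
```

TRR = 1.0 means the number of annotated loci equals the reference count
for every family; `automatic_precision` is the fraction of reference genes
recovered in the final GTF, and `supervised_precision` additionally counts
genes localized only in `matched_regions.gtf`.

Key thresholds are exposed on the command line: `--gensize` (maximum gene
span, default 50 000 bp), `--mincds` (minimum CDS length, default 200 bp)
and `--identity` (minimum hit identity, default 0.80). Genes whose span or
CDS length falls outside these ranges are skipped under defaults and
recovered when the thresholds are relaxed.

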