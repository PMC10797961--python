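"""Full-length toxin-CDS databases: loading, validation, clustering, merging.

A toxin database is the searchable reference set of the pipeline: every
record is a full-length coding sequence (canonical ATG start, canonical
terminal stop, codon-multiple length, no internal in-frame stop) carrying a
toxin-family label (SVMP, PLA2, CTL, ...). Redundancy in public sequence
sets is reduced by greedy identity clustering before annotation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import pairwise_identity

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
CDS_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class ToxinRecord:
    """One full-length toxin CDS with its family label."""

    id: str
    family: str
    cds: str

    @property
    def length(self) -> int:
        return len(self.cds)


@dataclass
class ValidationResult:
    """Outcome of full-length CDS validation; failures are coded, not raised."""

    valid: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class ToxinDatabase:
    """Ordered collection of unique-id ToxinRecords."""

    records: list[ToxinRecord] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in toxin database")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rec_id: str) -> ToxinRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


def validate_cds(seq: str, min_len: int = 200) -> ValidationResult:
    """Check that ``seq`` is a full-length CDS.

    Returns every applicable failure code (``bad_alphabet``, ``no_start``,
    ``no_terminal_stop``, ``not_codon_multiple``, ``internal_stop``,
    ``below_min_length``), not just the first.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    reasons: list[str] = []
    if not set(seq) <= CDS_ALPHABET:
        reasons.append("bad_alphabet")
    if not seq.startswith(START_CODON):
        reasons.append("no_start")
    if len(seq) < 3 or seq[-3:] not in STOP_CODONS:
        reasons.append("no_terminal_stop")
    if len(seq) % 3 != 0:
        reasons.append("not_codon_multiple")
    elif any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 3, 3)):
        reasons.append("internal_stop")
    if len(seq) < min_len:
        reasons.append("below_min_length")
    return ValidationResult(valid=not reasons, reasons=reasons)


def parse_family(header_id: str) -> str:
    """Family tag: token after the last ``|`` if present, else the id with a
    trailing copy-number suffix removed (``SVSP-7`` -> ``SVSP``,
    ``PLA2_3`` -> ``PLA2``)."""
    if "|" in header_id:
        return header_id.rsplit("|", 1)[1]
    return re.sub(r"[-_.]\d+$", "", header_id) or header_id


def read_fasta_db(path, min_cds_len: int = 200, source: str | None = None) -> ToxinDatabase:
    """Load a toxin database from FASTA, dropping invalid records with a warning."""
    records: list[ToxinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        res = validate_cds(seq, min_cds_len)
        if not res.valid:
            logger.warning("dropping %s: %s", rec.id, ",".join(res.reasons))
            continue
        rid = rec.id
        if rid in seen:
            logger.warning("dropping duplicate id %s", rid)
            continue
        seen.add(rid)
        records.append(ToxinRecord(id=rid, family=parse_family(rid), cds=seq))
    return ToxinDatabase(records=records, source=source or str(path))


def write_fasta_db(db: ToxinDatabase, path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    recs = [SeqRecord(Seq(r.cds), id=r.id, description="") for r in db]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


@dataclass
class Cluster:
    representative: ToxinRecord
    members: list[ToxinRecord]


def cluster_by_identity(db: ToxinDatabase, threshold: float = 0.99) -> list[Cluster]:
    """Greedy longest-first incremental clustering.

    Records are sorted by decreasing length (ties by id); each joins the
    first existing cluster whose representative shares global percent
    identity >= threshold, else founds a new cluster. The representative is
    the founding (longest) sequence.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(db.records, key=lambda r: (-r.length, r.id))
    clusters: list[Cluster] = []
    for rec in ordered:
        placed = False
        for cl in clusters:
            if pairwise_identity(rec.cds, cl.representative.cds) >= threshold:
                cl.members.append(rec)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec, members=[rec]))
    return clusters


def cluster_database(db: ToxinDatabase, threshold: float = 0.99) -> ToxinDatabase:
    """Reduce a database to cluster representatives (longest-first order)."""
    clusters = cluster_by_identity(db, threshold)
    return ToxinDatabase(
        records=[c.representative for c in clusters],
        source=f"{db.source}|clustered@{threshold}",
    )


def merge_databases(main: ToxinDatabase, custom: ToxinDatabase) -> ToxinDatabase:
    """Union of two databases.

    Exact-duplicate sequences are removed (first occurrence wins); id
    collisions between different sequences are resolved by deterministic
    suffixing of the later id.
    """
    records: list[ToxinRecord] = []
    seen_seq: set[str] = set()
    seen_id: set[str] = set()
    for rec in list(main.records) + list(custom.records):
        if rec.cds in seen_seq:
            continue
        seen_seq.add(rec.cds)
        rid = rec.id
        n = 1
        while rid in seen_id:
            n += 1
            rid = f"{rec.id}_{n}"
        seen_id.add(rid)
        records.append(ToxinRecord(id=rid, family=rec.family, cds=rec.cds))
    return ToxinDatabase(records=records, source=f"{main.source}+{custom.source}")


def write_manifest(db: ToxinDatabase, clusters: list[Cluster], path) -> None:
    """TSV manifest: id, family, length, cluster_id (cluster of membership)."""
    cluster_of: dict[str, str] = {}
    for i, cl in enumerate(clusters):
        for m in cl.members:
            cluster_of[m.id] = f"cluster_{i}"
    with open(path, "w") as fh:
        fh.write("id\tfamily\tlength\tcluster_id\n")
        for r in db:
            fh.write(f"{r.id}\t{r.family}\t{r.length}\t{cluster_of.get(r.id, 'NA')}\n")
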