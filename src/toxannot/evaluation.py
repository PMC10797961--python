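"""Annotation evaluation: toxin recovery rate, per-gene labels, precision.

The toxin recovery rate (TRR) of a family is the number of annotated loci
divided by the number reported in the reference annotation: 1 is an exact
match, >1 means extra loci were found, <1 means some were missed.
Per-gene labels compare the final annotation and the matched-regions
surface against a reference: ``matched_and_annotated`` (a final annotation
covers the reference gene), ``matched_but_not_annotated`` (only a matched
region covers it — recoverable by supervised inspection), ``not_matched``.
Automatic precision counts only the first class; supervised precision
counts the first two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

MATCHED_AND_ANNOTATED = "matched_and_annotated"
MATCHED_NOT_ANNOTATED = "matched_but_not_annotated"
NOT_MATCHED = "not_matched"


@dataclass(frozen=True)
class ReferenceGene:
    """Reference toxin gene: CDS footprint on the assembly."""

    gene_id: str
    family: str
    contig_id: str
    strand: str
    start: int
    end: int


@dataclass
class EvaluationReport:
    trr: dict[str, float | None]
    labels: dict[str, str]
    automatic_precision: float
    supervised_precision: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "trr": self.trr,
                "labels": self.labels,
                "automatic_precision": self.automatic_precision,
                "supervised_precision": self.supervised_precision,
            }, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tlabel\n")
            for gid in sorted(self.labels):
                fh.write(f"{gid}\t{self.labels[gid]}\n")


def toxin_recovery_rate(annotated: dict[str, int],
                        reported: dict[str, int]) -> dict[str, float | None]:
    """Per-family TRR = annotated / reported; ``None`` where reported == 0."""
    out: dict[str, float | None] = {}
    for fam in sorted(set(annotated) | set(reported)):
        a = annotated.get(fam, 0)
        r = reported.get(fam, 0)
        if a < 0 or r < 0:
            raise ValueError("negative count")
        out[fam] = None if r == 0 else a / r
    return out


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def label_against_reference(final, matched, reference: list[ReferenceGene],
                            min_overlap_frac: float = 0.50) -> dict[str, str]:
    """Label each reference gene by coverage of its CDS footprint.

    ``final`` is any iterable with contig_id/strand/start/end (gene models);
    ``matched`` likewise (matched regions). A reference gene counts as
    covered when a same-strand feature overlaps >= ``min_overlap_frac`` of
    its footprint.
    """
    labels: dict[str, str] = {}
    for ref in reference:
        need = min_overlap_frac * (ref.end - ref.start)
        def covered(features) -> bool:
            return any(
                f.contig_id == ref.contig_id and f.strand == ref.strand
                and _overlap(f.start, f.end, ref.start, ref.end) >= need
                for f in features
            )
        if covered(final):
            labels[ref.gene_id] = MATCHED_AND_ANNOTATED
        elif covered(matched):
            labels[ref.gene_id] = MATCHED_NOT_ANNOTATED
        else:
            labels[ref.gene_id] = NOT_MATCHED
    return labels


def precision(n_correct: int, n_total: int) -> float:
    """Fraction of reference genes recovered in the final annotation."""
    _check_counts(n_correct, n_total)
    return n_correct / n_total


def supervised_precision(n_correct: int, n_matched_only: int, n_total: int) -> float:
    """Fraction recovered after also counting matched-but-not-annotated genes."""
    _check_counts(n_correct + n_matched_only, n_total)
    return (n_correct + n_matched_only) / n_total


def _check_counts(n_good: int, n_total: int) -> None:
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_good <= n_total:
        raise ValueError("counts out of range")


def render_percent(fraction: float, decimals: int = 1) -> float:
    """Percent rendering, rounded half away from zero (82.4 for 42/51)."""
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100)).quantize(quant, rounding=ROUND_HALF_UP))


def evaluate(final, matched, reference: list[ReferenceGene],
             annotated_per_family: dict[str, int] | None = None,
             min_overlap_frac: float = 0.50) -> EvaluationReport:
    """Full evaluation of a pipeline run against a reference annotation."""
    labels = label_against_reference(final, matched, reference, min_overlap_frac)
    n_total = len(reference)
    n_corr = sum(1 for v in labels.values() if v == MATCHED_AND_ANNOTATED)
    n_only = sum(1 for v in labels.values() if v == MATCHED_NOT_ANNOTATED)
    if annotated_per_family is None:
        annotated_per_family = {}
        for m in final:
            fam = getattr(m, "family", None)
            if fam is not None:
                annotated_per_family[fam] = annotated_per_family.get(fam, 0) + 1
    reported = {}
    for ref in reference:
        reported[ref.family] = reported.get(ref.family, 0) + 1
    return EvaluationReport(
        trr=toxin_recovery_rate(annotated_per_family, reported),
        labels=labels,
        automatic_precision=precision(n_corr, n_total) if n_total else 0.0,
        supervised_precision=supervised_precision(n_corr, n_only, n_total) if n_total else 0.0,
    )
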