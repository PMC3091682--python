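"""Classify miRNAs as intergenic, exonic or intronic against gene models.

A miRNA is *intragenic* when its hairpin interval is fully contained in
some gene's transcript span (a locus straddling a gene boundary stays
intergenic). Among several containing genes the host is the same-strand
gene if any, otherwise the longest one, ties broken by smallest gene_id;
every ambiguous choice is logged. An intragenic miRNA is *exonic* when it
overlaps at least one basepair of any host exon and *intronic* otherwise,
in which case it is assigned the ordinal (1-based, 5'→3' in host
orientation) of the intron containing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomeAnnotation,
    MirnaLocus,
    derive_introns,
)

logger = logging.getLogger(__name__)

CLASSES = ("intronic", "exonic", "intergenic")


@dataclass(frozen=True)
class MirnaPlacement:
    """Classification of a single miRNA locus."""

    mirna_id: str
    mirna_class: str
    host_gene_id: str | None = None
    intron_ordinal: int | None = None
    same_strand: bool | None = None

    def __post_init__(self) -> None:
        if self.mirna_class not in CLASSES:
            raise ValueError(f"unknown class {self.mirna_class!r}")
        intragenic = self.mirna_class != "intergenic"
        if intragenic != (self.host_gene_id is not None):
            raise ValueError("host_gene_id present iff miRNA is intragenic")
        if (self.mirna_class == "intronic") != (self.intron_ordinal is not None):
            raise ValueError("intron_ordinal present iff class is intronic")
        if intragenic != (self.same_strand is not None):
            raise ValueError("same_strand present iff miRNA is intragenic")


def _choose_host(mirna: MirnaLocus, candidates: list[GeneModel]) -> GeneModel:
    same = [g for g in candidates if g.interval.strand == mirna.interval.strand]
    pool = same or candidates
    host = min(pool, key=lambda g: (-len(g.interval), g.gene_id))
    if len(candidates) > 1:
        logger.info(
            "miRNA %s contained in %d genes; host %s chosen (%s-strand rule)",
            mirna.mirna_id,
            len(candidates),
            host.gene_id,
            "same" if same else "longest",
        )
    return host


def classify_mirna(mirna: MirnaLocus, annotation: GenomeAnnotation) -> MirnaPlacement:
    """Classify one miRNA locus against the annotation."""
    candidates = annotation.genes_containing(mirna.interval)
    if not candidates:
        return MirnaPlacement(mirna.mirna_id, "intergenic")
    host = _choose_host(mirna, candidates)
    same_strand = mirna.interval.strand == host.interval.strand
    if any(e.overlaps(mirna.interval) for e in host.exons):
        return MirnaPlacement(
            mirna.mirna_id, "exonic", host.gene_id, same_strand=same_strand
        )
    ordinal = None
    for k, intron in enumerate(derive_introns(host), start=1):
        if intron.contains(mirna.interval):
            ordinal = k
            break
    if ordinal is None:
        # contained in the span, no exon overlap, yet in no single intron:
        # cannot happen for a well-formed model, but fail loudly if it does
        raise RuntimeError(
            f"miRNA {mirna.mirna_id} inside {host.gene_id} matches no intron"
        )
    return MirnaPlacement(
        mirna.mirna_id, "intronic", host.gene_id, ordinal, same_strand
    )


def classify_all(annotation: GenomeAnnotation) -> list[MirnaPlacement]:
    """Classify every miRNA in the annotation, preserving input order."""
    return [classify_mirna(m, annotation) for m in annotation.mirnas.values()]


@dataclass(frozen=True)
class ClassificationSummary:
    """Per-class counts and percentages plus the intragenic strand split."""

    label: str
    counts: dict[str, int]
    percentages: dict[str, float]
    same_strand: int | None
    opposite_strand: int | None
    same_strand_pct: float | None
    opposite_strand_pct: float | None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def summarize_classification(
    placements: list[MirnaPlacement], label: str = ""
) -> ClassificationSummary:
    """Table-style summary: class counts, one-decimal percentages, strand split."""
    if not placements:
        raise ValueError("no placements to summarize")
    counts = {c: sum(1 for p in placements if p.mirna_class == c) for c in CLASSES}
    total = len(placements)
    pct = {c: round(100.0 * n / total, 1) for c, n in counts.items()}
    intragenic = [p for p in placements if p.mirna_class != "intergenic"]
    if intragenic:
        same = sum(1 for p in intragenic if p.same_strand)
        opposite = len(intragenic) - same
        same_pct = round(100.0 * same / len(intragenic), 1)
        opp_pct = round(100.0 * opposite / len(intragenic), 1)
    else:
        same = opposite = same_pct = opp_pct = None
    return ClassificationSummary(
        label=label,
        counts=counts,
        percentages=pct,
        same_strand=same,
        opposite_strand=opposite,
        same_strand_pct=same_pct,
        opposite_strand_pct=opp_pct,
    )


def placements_to_frame(
    placements: list[MirnaPlacement], annotation: GenomeAnnotation | None = None
) -> pd.DataFrame:
    """One row per miRNA, ready for TSV export."""
    rows = []
    for p in placements:
        mirna_strand = host_strand = None
        if annotation is not None:
            mirna_strand = annotation.mirnas[p.mirna_id].interval.strand
            if p.host_gene_id is not None:
                host_strand = annotation.genes[p.host_gene_id].interval.strand
        rows.append(
            {
                "mirna_id": p.mirna_id,
                "class": p.mirna_class,
                "host_gene_id": p.host_gene_id,
                "intron_ordinal": p.intron_ordinal,
                "mirna_strand": mirna_strand,
                "host_strand": host_strand,
                "same_strand": p.same_strand,
            }
        )
    return pd.DataFrame(rows)


def write_placements(
    placements: list[MirnaPlacement],
    path: str | Path,
    annotation: GenomeAnnotation | None = None,
) -> None:
    placements_to_frame(placements, annotation).to_csv(path, sep="\t", index=False)
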