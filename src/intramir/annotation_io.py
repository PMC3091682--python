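"""Gene models, miRNA loci and the file dialects that carry them.

Internal coordinates are 0-based half-open throughout; conversions to and
from 1-based inclusive conventions (GFF3, miRNA GFF) happen only at the
file boundary. Sequences are normalized to uppercase RNA (``T`` → ``U``)
on ingest so that downstream motif scans (the AUUUA pentamer) are
well-defined.

Supported gene-model dialects:

* ``gff3`` — one ``mRNA`` feature per transcript with ``exon`` and
  (optionally) ``CDS`` children;
* ``bed12`` — one line per transcript, ``name`` field ``gene_id|symbol``,
  ``thickStart == thickEnd`` meaning "non-coding";
* ``refflat_tsv`` — a refFlat-like table (symbol, gene_id, chrom, strand,
  txStart, txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds) with
  UCSC's 0-based half-open coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

GENE_MODEL_FORMATS = ("gff3", "bed12", "refflat_tsv")

REFFLAT_COLUMNS = (
    "symbol",
    "gene_id",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
)


class AnnotationError(ValueError):
    """Raised for malformed annotation files or inconsistent gene models."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """One transcript: exon structure, optional CDS, optional UTR sequences."""

    gene_id: str
    symbol: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds_start: int | None = None
    cds_end: int | None = None
    utr5_sequence: str | None = None
    utr3_sequence: str | None = None

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene model needs >= 1 exon")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or exon.strand != self.interval.strand:
                raise AnnotationError(
                    f"{self.gene_id}: exon {exon} not on transcript chrom/strand"
                )
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise AnnotationError(
                    f"{self.gene_id}: exon {exon.start}-{exon.end} outside "
                    f"transcript span {self.interval.start}-{self.interval.end}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise AnnotationError(
                    f"{self.gene_id}: exons unsorted or overlapping at {exon.start}"
                )
            prev_end = exon.end
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"{self.gene_id}: CDS must have both ends or neither")
        if self.cds_start is not None:
            if not (
                self.interval.start <= self.cds_start < self.cds_end <= self.interval.end
            ):
                raise AnnotationError(
                    f"{self.gene_id}: CDS {self.cds_start}-{self.cds_end} outside span"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def total_length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class MirnaLocus:
    """One miRNA hairpin locus."""

    mirna_id: str
    interval: GenomicInterval


@dataclass
class GenomeAnnotation:
    """Gene models plus miRNA loci with a per-chromosome interval index."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    mirnas: dict[str, MirnaLocus] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] | None = field(default=None, repr=False)

    @classmethod
    def from_lists(
        cls,
        genes: Iterable[GeneModel] = (),
        mirnas: Iterable[MirnaLocus] = (),
    ) -> "GenomeAnnotation":
        ann = cls()
        for g in genes:
            ann.add_gene(g)
        for m in mirnas:
            ann.add_mirna(m)
        return ann

    def add_gene(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id: {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        self._trees = None

    def add_mirna(self, mirna: MirnaLocus) -> None:
        if mirna.mirna_id in self.mirnas:
            raise AnnotationError(f"duplicate mirna_id: {mirna.mirna_id}")
        self.mirnas[mirna.mirna_id] = mirna

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for gene in self.genes.values():
                iv = gene.interval
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, gene.gene_id
                )
            self._trees = trees
        return self._trees

    def genes_overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        tree = self._index().get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return [self.genes[h.data] for h in hits]

    def genes_containing(self, interval: GenomicInterval) -> list[GeneModel]:
        """Genes whose transcript span fully contains ``interval``."""
        return [
            g for g in self.genes_overlapping(interval) if g.interval.contains(interval)
        ]


# ---------------------------------------------------------------------------
# derived structure


def derive_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Introns of ``gene`` ordered 5'→3' in gene orientation.

    The returned list index + 1 is the intron ordinal: for a "-" strand
    gene, ordinal 1 is the gap with the largest genomic coordinates.
    A single-exon gene has no introns.
    """
    gaps = [
        GenomicInterval(gene.interval.chrom, a.end, b.start, gene.interval.strand)
        for a, b in zip(gene.exons, gene.exons[1:])
    ]
    if gene.interval.strand == "-":
        gaps.reverse()
    return gaps


def derive_utr_lengths(gene: GeneModel) -> tuple[int, int]:
    """(5'-UTR, 3'-UTR) lengths in exonic basepairs. Requires a CDS."""
    if not gene.is_coding:
        raise AnnotationError(f"{gene.gene_id}: no CDS, UTR lengths undefined")
    cs, ce = gene.cds_start, gene.cds_end
    if not any(e.start <= cs < e.end for e in gene.exons) or not any(
        e.start < ce <= e.end for e in gene.exons
    ):
        raise AnnotationError(f"{gene.gene_id}: CDS boundaries outside exons")
    left = sum(max(0, min(e.end, cs) - e.start) for e in gene.exons)
    right = sum(max(0, e.end - max(e.start, ce)) for e in gene.exons)
    if gene.interval.strand == "+":
        return left, right
    return right, left


def select_canonical(genes: Sequence[GeneModel]) -> GeneModel:
    """One transcript per symbol: greatest exonic length, ties by gene_id."""
    if not genes:
        raise AnnotationError("empty transcript group")
    return min(genes, key=lambda g: (-g.exonic_length, g.gene_id))


def collapse_to_canonical(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Keep one canonical transcript per symbol."""
    by_symbol: dict[str, list[GeneModel]] = {}
    for g in annotation.genes.values():
        by_symbol.setdefault(g.symbol, []).append(g)
    return GenomeAnnotation.from_lists(
        (select_canonical(group) for group in by_symbol.values()),
        annotation.mirnas.values(),
    )


# ---------------------------------------------------------------------------
# sequences


_RNA_OK = set("ACGUN")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; reject non-nucleotide letters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_OK
    if bad:
        raise AnnotationError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def read_utr_fasta(path: str | Path) -> dict[tuple[str, str], str]:
    """Read UTR sequences keyed ``gene_id:utr3`` / ``gene_id:utr5``.

    Returns a mapping (gene_id, "utr3"|"utr5") → RNA sequence.
    """
    out: dict[tuple[str, str], str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if ":" not in rec.id:
            raise AnnotationError(f"FASTA id {rec.id!r} lacks ':utr3'/':utr5' suffix")
        gene_id, which = rec.id.rsplit(":", 1)
        if which not in ("utr3", "utr5"):
            raise AnnotationError(f"FASTA id {rec.id!r}: unknown suffix {which!r}")
        out[(gene_id, which)] = normalize_rna(str(rec.seq))
    return out


def write_utr_fasta(
    sequences: dict[tuple[str, str], str], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{gene_id}:{which}", description="")
        for (gene_id, which), seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def attach_utr_sequences(
    annotation: GenomeAnnotation, sequences: dict[tuple[str, str], str]
) -> None:
    """Attach UTR sequences to the matching gene models, in place."""
    for (gene_id, which), seq in sequences.items():
        gene = annotation.genes.get(gene_id)
        if gene is None:
            logger.warning("UTR sequence for unknown gene %s ignored", gene_id)
            continue
        if which == "utr3":
            gene.utr3_sequence = seq
        else:
            gene.utr5_sequence = seq


# ---------------------------------------------------------------------------
# gene model readers/writers


def read_gene_models(path: str | Path, format: str) -> GenomeAnnotation:
    """Read gene models from ``path`` in the declared dialect."""
    if format not in GENE_MODEL_FORMATS:
        raise AnnotationError(
            f"unknown format {format!r}; expected one of {GENE_MODEL_FORMATS}"
        )
    reader = {
        "gff3": _read_gff3,
        "bed12": _read_bed12,
        "refflat_tsv": _read_refflat,
    }[format]
    genes = reader(Path(path))
    if not genes:
        raise AnnotationError(f"{path}: no gene records found")
    ann = GenomeAnnotation()
    for g in genes:
        ann.add_gene(g)
    return ann


def write_gene_models(
    annotation: GenomeAnnotation, path: str | Path, format: str
) -> None:
    if format not in GENE_MODEL_FORMATS:
        raise AnnotationError(
            f"unknown format {format!r}; expected one of {GENE_MODEL_FORMATS}"
        )
    writer = {
        "gff3": _write_gff3,
        "bed12": _write_bed12,
        "refflat_tsv": _write_refflat,
    }[format]
    writer(list(annotation.genes.values()), Path(path))


def _fail(path: Path, lineno: int, msg: str) -> None:
    raise AnnotationError(f"{path}:{lineno}: {msg}")


def _read_refflat(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(REFFLAT_COLUMNS):
                _fail(path, lineno, f"expected {len(REFFLAT_COLUMNS)} columns")
            (symbol, gene_id, chrom, strand, tx_s, tx_e, cds_s, cds_e,
             n_ex, ex_starts, ex_ends) = fields
            try:
                tx_s, tx_e, cds_s, cds_e, n_ex = map(int, (tx_s, tx_e, cds_s, cds_e, n_ex))
                starts = [int(x) for x in ex_starts.rstrip(",").split(",")]
                ends = [int(x) for x in ex_ends.rstrip(",").split(",")]
            except ValueError:
                _fail(path, lineno, "non-integer coordinate field")
            if len(starts) != n_ex or len(ends) != n_ex:
                _fail(path, lineno, "exonCount does not match exon lists")
            try:
                exons = tuple(
                    GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
                )
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        symbol=symbol,
                        interval=GenomicInterval(chrom, tx_s, tx_e, strand),
                        exons=exons,
                        cds_start=cds_s if cds_s != cds_e else None,
                        cds_end=cds_e if cds_s != cds_e else None,
                    )
                )
            except AnnotationError as exc:
                _fail(path, lineno, str(exc))
    return genes


def _write_refflat(genes: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(REFFLAT_COLUMNS) + "\n")
        for g in genes:
            cds_s = g.cds_start if g.is_coding else g.interval.end
            cds_e = g.cds_end if g.is_coding else g.interval.end
            fh.write(
                "\t".join(
                    [
                        g.symbol,
                        g.gene_id,
                        g.interval.chrom,
                        g.interval.strand,
                        str(g.interval.start),
                        str(g.interval.end),
                        str(cds_s),
                        str(cds_e),
                        str(len(g.exons)),
                        ",".join(str(e.start) for e in g.exons) + ",",
                        ",".join(str(e.end) for e in g.exons) + ",",
                    ]
                )
                + "\n"
            )


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                _fail(path, lineno, "BED12 requires 12 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            thick_s, thick_e, _rgb, block_n = fields[6:10]
            try:
                start, end = int(start), int(end)
                thick_s, thick_e, block_n = int(thick_s), int(thick_e), int(block_n)
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                _fail(path, lineno, "non-integer coordinate field")
            if len(sizes) != block_n or len(offsets) != block_n:
                _fail(path, lineno, "blockCount does not match block lists")
            gene_id, _, symbol = name.partition("|")
            symbol = symbol or gene_id
            try:
                exons = tuple(
                    GenomicInterval(chrom, start + off, start + off + size, strand)
                    for off, size in zip(offsets, sizes)
                )
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        symbol=symbol,
                        interval=GenomicInterval(chrom, start, end, strand),
                        exons=exons,
                        cds_start=thick_s if thick_s != thick_e else None,
                        cds_end=thick_e if thick_s != thick_e else None,
                    )
                )
            except AnnotationError as exc:
                _fail(path, lineno, str(exc))
    return genes


def _write_bed12(genes: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            thick_s = g.cds_start if g.is_coding else g.interval.start
            thick_e = g.cds_end if g.is_coding else g.interval.start
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        str(g.interval.start),
                        str(g.interval.end),
                        f"{g.gene_id}|{g.symbol}",
                        "0",
                        g.interval.strand,
                        str(thick_s),
                        str(thick_e),
                        "0",
                        str(len(g.exons)),
                        ",".join(str(len(e)) for e in g.exons) + ",",
                        ",".join(str(e.start - g.interval.start) for e in g.exons) + ",",
                    ]
                )
                + "\n"
            )


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, value = chunk.partition("=")
        else:  # GFF2-style:  key "value"
            key, _, value = chunk.partition(" ")
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


def _read_gff3(path: Path) -> list[GeneModel]:
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                _fail(path, lineno, "GFF3 requires 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr_text = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            attrs = _parse_gff_attributes(attr_text)
            if ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                if tid is None:
                    _fail(path, lineno, "transcript feature lacks ID attribute")
                if tid in transcripts:
                    _fail(path, lineno, f"duplicate transcript id {tid!r}")
                transcripts[tid] = {
                    "symbol": attrs.get("Name", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "start": start_i - 1,  # 1-based inclusive -> 0-based half-open
                    "end": end_i,
                    "exons": [],
                    "cds": [],
                }
                order.append(tid)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None or parent not in transcripts:
                    _fail(path, lineno, f"{ftype} without known Parent")
                key = "exons" if ftype == "exon" else "cds"
                transcripts[parent][key].append((start_i - 1, end_i))
    genes: list[GeneModel] = []
    for tid in order:
        t = transcripts[tid]
        exon_coords = sorted(t["exons"])
        if not exon_coords:
            raise AnnotationError(f"{path}: transcript {tid} has no exons")
        cds_start = cds_end = None
        if t["cds"]:
            cds_start = min(s for s, _ in t["cds"])
            cds_end = max(e for _, e in t["cds"])
        genes.append(
            GeneModel(
                gene_id=tid,
                symbol=t["symbol"],
                interval=GenomicInterval(t["chrom"], t["start"], t["end"], t["strand"]),
                exons=tuple(
                    GenomicInterval(t["chrom"], s, e, t["strand"])
                    for s, e in exon_coords
                ),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return genes


def _write_gff3(genes: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tintramir\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id};Name={g.symbol}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{iv.chrom}\tintramir\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{iv.strand}\t.\tParent={g.gene_id}\n"
                )
            if g.is_coding:
                for e in g.exons:
                    s = max(e.start, g.cds_start)
                    t = min(e.end, g.cds_end)
                    if s < t:
                        fh.write(
                            f"{iv.chrom}\tintramir\tCDS\t{s + 1}\t{t}\t.\t"
                            f"{iv.strand}\t0\tParent={g.gene_id}\n"
                        )


# ---------------------------------------------------------------------------
# miRNA GFF


def read_mirna_gff(path: str | Path) -> list[MirnaLocus]:
    """Read miRNA hairpin loci from a (miRBase-dialect) GFF file."""
    path = Path(path)
    loci: list[MirnaLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                _fail(path, lineno, "GFF requires 9 columns")
            chrom, _src, _ftype, start, end, _score, strand, _frame, attr_text = fields[:9]
            if strand not in ("+", "-"):
                _fail(path, lineno, f"missing or invalid strand {strand!r}")
            attrs = _parse_gff_attributes(attr_text)
            mirna_id = attrs.get("ID") or attrs.get("Name")
            if mirna_id is None:
                _fail(path, lineno, "record lacks ID/Name attribute")
            if mirna_id in seen:
                _fail(path, lineno, f"duplicate mirna_id {mirna_id!r}")
            seen.add(mirna_id)
            loci.append(
                MirnaLocus(
                    mirna_id=mirna_id,
                    interval=GenomicInterval(chrom, int(start) - 1, int(end), strand),
                )
            )
    if not loci:
        logger.warning("%s: no miRNA records found", path)
    return loci


def write_mirna_gff(loci: Iterable[MirnaLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in loci:
            iv = m.interval
            fh.write(
                f"{iv.chrom}\tintramir\tmiRNA_primary_transcript\t{iv.start + 1}\t"
                f"{iv.end}\t.\t{iv.strand}\t.\tID={m.mirna_id};Name={m.mirna_id}\n"
            )
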