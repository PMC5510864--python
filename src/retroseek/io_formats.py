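"""Readers/writers for the standard formats the pipeline touches.

All coordinates inside the package are 0-based half-open (BED-like).
Conversion from 1-based inclusive conventions (GTF/GFF3, SAM POS) happens
only here, at the I/O boundary.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open. Strand '.' means strand-agnostic."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start},{self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicInterval") -> int:
        """Gap between intervals on the same chromosome; 0 if they overlap or touch."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class AlignmentRecord:
    """One read alignment (or unmapped read) in the package's internal model."""

    read_id: str
    mapped: bool
    interval: GenomicInterval | None = None
    mapq: int = 0
    mate_interval: GenomicInterval | None = None
    is_read1: bool = True
    cigar: list[tuple[str, int]] = field(default_factory=list)
    n_mismatch: int = 0
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.mapped and self.interval is None:
            raise ValueError("mapped record requires an interval")
        if self.n_mismatch < 0:
            raise ValueError("n_mismatch must be >= 0")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# --- annotation -------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]*)")

_CODING_BIOTYPES = {"protein_coding"}


def _parse_attributes(attr_field: str) -> dict[str, str]:
    # GFF3 uses key=value; GTF uses key "value". Try GFF3 first (unambiguous '=').
    if "=" in attr_field.split(";", 1)[0]:
        return dict(_GFF3_ATTR.findall(attr_field))
    return dict(_GTF_ATTR.findall(attr_field))


def read_annotation(path: str | Path, coding_only: bool = True) -> dict[str, list[GenomicInterval]]:
    """Parse a GTF/GFF3 file into {gene_id: ordered distinct exon intervals}.

    Exons are pooled at the gene level across transcripts, deduplicated, and
    sorted by genomic coordinate. 1-based inclusive input coordinates are
    converted to 0-based half-open. When ``coding_only`` is set, exons are
    restricted to protein-coding genes/transcripts (biotype attributes when
    present; otherwise all exons are kept).
    """
    genes: dict[str, set[GenomicInterval]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed feature line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields[:9]
            if ftype.lower() != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"malformed feature line {lineno}: non-integer coordinates") from exc
            attr = _parse_attributes(attrs)
            gene_id = attr.get("gene_id") or attr.get("Parent") or attr.get("ID")
            if gene_id is None:
                raise ValueError(f"malformed feature line {lineno}: no gene_id/Parent attribute")
            if coding_only:
                biotype = (
                    attr.get("gene_type")
                    or attr.get("gene_biotype")
                    or attr.get("transcript_type")
                    or attr.get("transcript_biotype")
                )
                if biotype is not None and biotype not in _CODING_BIOTYPES:
                    continue
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand if strand in "+-" else ".")
            genes.setdefault(gene_id, set()).add(iv)
    return {g: sorted(ivs, key=lambda iv: (iv.start, iv.end)) for g, ivs in sorted(genes.items())}


# --- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str] | Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    with _open_text(path, "wt") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- SAM --------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=XB"


def _record_from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    mapped = not seg.is_unmapped
    interval = None
    if mapped:
        interval = GenomicInterval(
            seg.reference_name,
            seg.reference_start,
            seg.reference_end if seg.reference_end is not None else seg.reference_start + 1,
            "-" if seg.is_reverse else "+",
        )
    mate_interval = None
    if seg.is_paired and not seg.mate_is_unmapped and seg.next_reference_name is not None:
        mstart = seg.next_reference_start
        mlen = seg.query_length or len(seg.query_sequence or "") or 1
        mate_interval = GenomicInterval(
            seg.next_reference_name, mstart, mstart + mlen, "-" if seg.mate_is_reverse else "+"
        )
    cigar = []
    if seg.cigartuples:
        cigar = [(_CIGAR_OPS[op], length) for op, length in seg.cigartuples]
    try:
        nm = int(seg.get_tag("NM"))
    except KeyError:
        nm = 0
    return AlignmentRecord(
        read_id=seg.query_name,
        mapped=mapped,
        interval=interval,
        mapq=seg.mapping_quality,
        mate_interval=mate_interval,
        is_read1=not seg.is_read2,
        cigar=cigar,
        n_mismatch=nm,
        sequence=seg.query_sequence or "",
    )


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM file (flags decoded; unmapped kept)."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            yield _record_from_pysam(seg)


def write_sam(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    references: dict[str, int],
) -> None:
    """Write AlignmentRecords to SAM. ``references`` maps chrom -> length."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    ref_ids = {name: i for i, name in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.query_sequence = rec.sequence or None
            flag = 0
            if rec.mate_interval is not None or not rec.is_read1:
                flag |= 0x1  # paired
                flag |= 0x40 if rec.is_read1 else 0x80
            if not rec.mapped:
                flag |= 0x4
            elif rec.interval is not None and rec.interval.strand == "-":
                flag |= 0x10
            if rec.mate_interval is not None and rec.mate_interval.strand == "-":
                flag |= 0x20
            seg.flag = flag
            if rec.mapped and rec.interval is not None:
                seg.reference_id = ref_ids[rec.interval.chrom]
                seg.reference_start = rec.interval.start
                seg.mapping_quality = rec.mapq
                if rec.cigar:
                    seg.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
                elif rec.sequence:
                    seg.cigarstring = f"{len(rec.sequence)}M"
                seg.set_tag("NM", rec.n_mismatch)
            if rec.mate_interval is not None:
                seg.next_reference_id = ref_ids[rec.mate_interval.chrom]
                seg.next_reference_start = rec.mate_interval.start
            out.write(seg)


# --- BED --------------------------------------------------------------------

def read_bed(path: str | Path, known_chroms: set[str] | None = None) -> list[GenomicInterval]:
    """Read BED (>=3 columns, already 0-based half-open) into intervals.

    Lines on chromosomes absent from ``known_chroms`` (when given) are
    skipped with a logged warning rather than raising.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if known_chroms is not None and chrom not in known_chroms:
                logger.warning("BED line %d: unknown chromosome %r, skipped", lineno, chrom)
                continue
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names: Iterable[str] | None = None) -> None:
    names_list = list(names) if names is not None else None
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            name = names_list[i] if names_list else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# --- tables -----------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]
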