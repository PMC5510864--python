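"""Exon-junction library construction.

A retrocopy is an intron-less gene copy, so reads from its interior cross
exon-exon boundaries that do not exist in the reference genome. The true
library enumerates candidate junction sequences by joining flank segments of
exon pairs within each gene, in transcription order. Decoy libraries apply
the identical construction to coordinate-shifted (fake) exons; any read
calling against a decoy is a known false positive, which drives calling
parameter tuning and FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .io_formats import GenomicInterval, reverse_complement, write_fasta, _open_text

FLANK_LEN = 100
DECOY_SHIFTS = (1, 2, 3, 6, 12)


@dataclass(frozen=True)
class ExonSegment:
    """The up-to-100-base flank of one exon adjacent to a splice site.

    ``interval`` is the genomic span of the flank itself (not the whole
    exon); two junctions "share a segment" when they use the same flank.
    """

    gene_id: str
    interval: GenomicInterval
    flank_len: int

    def __post_init__(self) -> None:
        if not (1 <= self.flank_len <= FLANK_LEN):
            raise ValueError("flank_len must be in [1, 100]")
        if self.flank_len != len(self.interval):
            raise ValueError("flank_len must equal interval length")


@dataclass(frozen=True)
class ExonJunction:
    junction_id: str
    gene_id: str
    upstream: ExonSegment
    downstream: ExonSegment
    sequence: str
    junction_offset: int  # bases contributed by the upstream segment

    def __post_init__(self) -> None:
        if len(self.sequence) != self.upstream.flank_len + self.downstream.flank_len:
            raise ValueError("sequence length must equal sum of flank lengths")
        if self.junction_offset != self.upstream.flank_len:
            raise ValueError("junction_offset must equal upstream flank_len")


@dataclass
class JunctionLibrary:
    kind: str  # "true" or "decoy"
    junctions: list[ExonJunction]
    e: int = 0  # decoy shift; 0 for the true library

    def __post_init__(self) -> None:
        if self.kind == "decoy" and self.e not in DECOY_SHIFTS:
            raise ValueError(f"decoy shift must be in {DECOY_SHIFTS}")
        ids = [j.junction_id for j in self.junctions]
        if len(ids) != len(set(ids)):
            raise ValueError("junction_ids must be unique")

    def __len__(self) -> int:
        return len(self.junctions)

    def by_id(self) -> dict[str, ExonJunction]:
        return {j.junction_id: j for j in self.junctions}


def _flank_interval(exon: GenomicInterval, flank_len: int, donor_side: bool) -> GenomicInterval:
    """Genomic span of the flank adjacent to the splice site being joined.

    ``donor_side`` marks the transcriptionally-upstream exon (its 3' end
    feeds the junction); for the downstream exon the 5' start does.
    """
    at_end = donor_side if exon.strand != "-" else not donor_side
    if at_end:
        return GenomicInterval(exon.chrom, exon.end - flank_len, exon.end, exon.strand)
    return GenomicInterval(exon.chrom, exon.start, exon.start + flank_len, exon.strand)


def _exon_seq(genome: dict[str, str], iv: GenomicInterval) -> str:
    """Exon sequence in transcript orientation (reverse-complemented on '-')."""
    seq = genome[iv.chrom][iv.start : iv.end]
    return reverse_complement(seq) if iv.strand == "-" else seq


def _build_library(
    genes: dict[str, list[GenomicInterval]],
    genome: dict[str, str],
    kind: str,
    e: int = 0,
) -> JunctionLibrary:
    junctions: list[ExonJunction] = []
    seen_sequences: set[str] = set()
    tag = "J" if kind == "true" else f"D{e}"
    for gene_id, exons in genes.items():
        if e:
            exons = [
                GenomicInterval(iv.chrom, iv.start + e, iv.end - e, iv.strand)
                for iv in exons
                if iv.end - e > iv.start + e
            ]
        if len(exons) < 2:
            continue
        minus = exons[0].strand == "-"
        # transcription order: genomic order for '+', reversed for '-'
        ordered = list(reversed(exons)) if minus else list(exons)
        tx_seqs = [_exon_seq(genome, iv) for iv in ordered]
        for i in range(len(ordered) - 1):
            for j in range(i + 1, len(ordered)):
                up_len = min(FLANK_LEN, len(ordered[i]))
                down_len = min(FLANK_LEN, len(ordered[j]))
                seq = tx_seqs[i][-up_len:] + tx_seqs[j][:down_len]
                if seq in seen_sequences:
                    continue  # duplicate exon structures across transcripts
                seen_sequences.add(seq)
                up = ExonSegment(gene_id, _flank_interval(ordered[i], up_len, donor_side=True), up_len)
                down = ExonSegment(gene_id, _flank_interval(ordered[j], down_len, donor_side=False), down_len)
                junctions.append(
                    ExonJunction(
                        junction_id=f"{tag}:{gene_id}:{i+1}-{j+1}",
                        gene_id=gene_id,
                        upstream=up,
                        downstream=down,
                        sequence=seq,
                        junction_offset=up_len,
                    )
                )
    return JunctionLibrary(kind=kind, junctions=junctions, e=e)


def build_true_library(genes: dict[str, list[GenomicInterval]], genome: dict[str, str]) -> JunctionLibrary:
    """All ordered exon pairs (i<j in transcription order) per gene, spliced.

    Each junction sequence is the last ``flank_len`` bases of the upstream
    exon followed by the first ``flank_len`` bases of the downstream exon, in
    transcript orientation (minus-strand genes are reverse-complemented).
    Non-adjacent pairs are included because retrocopies are frequently
    5'-truncated and may skip exons. Genes with a single exon contribute
    nothing.
    """
    return _build_library(genes, genome, "true")


def build_decoy_library(
    genes: dict[str, list[GenomicInterval]], genome: dict[str, str], e: int
) -> JunctionLibrary:
    """Identical pairing logic applied to exons shifted inward by ``e`` bases
    on both sides (start+e, end−e); shifted exons of non-positive length drop.
    """
    if e not in DECOY_SHIFTS:
        raise ValueError(f"e must be one of {DECOY_SHIFTS}")
    return _build_library(genes, genome, "decoy", e=e)


def build_decoy_libraries(
    genes: dict[str, list[GenomicInterval]], genome: dict[str, str]
) -> list[JunctionLibrary]:
    return [build_decoy_library(genes, genome, e) for e in DECOY_SHIFTS]


def write_library_fasta(lib: JunctionLibrary, path: str | Path) -> None:
    """One FASTA record per junction; header encodes id, gene and offset."""
    records = (
        (f"{j.junction_id} gene_id={j.gene_id} offset={j.junction_offset}", j.sequence)
        for j in lib.junctions
    )
    write_fasta(records, path)


def read_library_fasta(path: str | Path) -> list[tuple[str, str, int, str]]:
    """Parse back (junction_id, gene_id, offset, sequence) from library FASTA."""
    out = []
    name, desc, chunks = None, "", []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out.append((name, desc, "".join(chunks)))
                parts = line[1:].split(None, 1)
                name = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
            else:
                chunks.append(line)
        if name is not None:
            out.append((name, desc, "".join(chunks)))
    parsed = []
    for name, desc, seq in out:
        attrs = dict(kv.split("=", 1) for kv in desc.split() if "=" in kv)
        parsed.append((name, attrs.get("gene_id", ""), int(attrs.get("offset", 0)), seq))
    return parsed


def write_library_manifest(lib: JunctionLibrary, path: str | Path) -> None:
    import pandas as pd

    from .io_formats import write_table

    rows = [
        {
            "junction_id": j.junction_id,
            "gene_id": j.gene_id,
            "up_chrom": j.upstream.interval.chrom,
            "up_start": j.upstream.interval.start,
            "up_end": j.upstream.interval.end,
            "down_start": j.downstream.interval.start,
            "down_end": j.downstream.interval.end,
            "offset": j.junction_offset,
        }
        for j in lib.junctions
    ]
    write_table(pd.DataFrame(rows), path)
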