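"""Synthetic genomes, cohorts and reads for exercising the pipeline.

Everything the calling and analysis stages consume can be generated here
with no external downloads: a toy genome with multi-exon protein-coding
genes, planted retrocopy alleles (spliced exons with optional 5'
truncation, poly-A tail, target-site duplication and optional L1
co-insertion), exome reads spanning exon-exon junctions, whole-genome read
pairs that turn discordant at insertion sites, and a multi-population
carrier cohort with configurable allele frequencies and expression
effects.

Reads are emitted with truth-consistent coordinates directly (no external
aligner): a junction-spanning exome read appears in the unmapped pool with
its true transcript placement recorded, and a whole-genome pair straddling
a planted insertion is emitted with the genomic-side read at its flank
coordinate and the insert-side read placed at its parent-gene exon
coordinate. Reads landing in poly-A or L1 portions of an insert are
treated as unplaceable, which is what makes long L1 co-insertions surface
as single-sided events downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, GenomicInterval, reverse_complement

BASES = np.array(list("ACGT"))

# 1000 Genomes-style population codes grouped into five continental superpopulations
POPULATIONS = {
    "AFR": ["ACB", "ASW", "ESN", "GWD", "LWK", "MSL", "YRI"],
    "AMR": ["CLM", "MXL", "PEL", "PUR"],
    "EAS": ["CDX", "CHB", "CHS", "JPT", "KHV"],
    "EUR": ["CEU", "FIN", "GBR", "IBS", "TSI"],
    "SAS": ["BEB", "GIH", "ITU", "PJL", "STU"],
}


def superpop_map() -> dict[str, str]:
    return {pop: sp for sp, pops in POPULATIONS.items() for pop in pops}


def all_populations() -> list[str]:
    return [pop for pops in POPULATIONS.values() for pop in pops]


@dataclass(frozen=True)
class RetrocopyEvent:
    parent_gene: str
    first_exon: int  # 0-based index into transcription order: exons[first_exon:] retained
    insertion_site: GenomicInterval  # 1 bp point interval at the target site
    orientation: str = "+"
    polyA_len: int = 30
    tsd_len: int = 12
    l1_co_insertion: tuple[str, int] | None = None  # (subfamily label, length)

    def __post_init__(self) -> None:
        if self.first_exon < 0:
            raise ValueError("first_exon must be >= 0 (5' truncation only)")
        if self.tsd_len < 0 or self.polyA_len < 0:
            raise ValueError("tsd_len and polyA_len must be >= 0")
        if self.orientation not in "+-":
            raise ValueError("orientation must be + or -")


@dataclass
class CohortDesign:
    populations: list[str]
    superpop_map: dict[str, str]
    n_per_pop: int
    gene_pop_freq: pd.DataFrame  # genes x populations, in [0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_pop < 1:
            raise ValueError("n_per_pop must be >= 1")
        if ((self.gene_pop_freq < 0) | (self.gene_pop_freq > 1)).any().any():
            raise ValueError("frequencies must lie in [0, 1]")


# --- genome and annotation --------------------------------------------------


def make_genome(
    seed: int = 0,
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    n_gaps_per_chrom: int = 2,
    gap_len: int = 5_000,
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Uniform-base toy genome with a few N-gap regions per chromosome."""
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    gaps: list[GenomicInterval] = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        seq = rng.choice(BASES, size=chrom_len)
        for g in range(n_gaps_per_chrom):
            start = int(rng.integers(0, chrom_len - gap_len))
            seq[start : start + gap_len] = "N"
            gaps.append(GenomicInterval(chrom, start, start + gap_len))
        genome[chrom] = "".join(seq)
    return genome, gaps


def make_annotation(
    genome: Mapping[str, str],
    n_genes: int = 30,
    exons_per_gene: int = 5,
    exon_len: int = 250,
    intron_len: int = 300,
    seed: int = 0,
    margin: int = 20_000,
) -> dict[str, list[GenomicInterval]]:
    """Evenly spaced multi-exon genes on alternating strands.

    Genes are laid out deterministically with wide spacing so planted
    insertion sites stay >= 1 kb from every gene; strand alternates so both
    splice orientations are exercised.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    genes: dict[str, list[GenomicInterval]] = {}
    per_chrom = -(-n_genes // len(chroms))  # ceil
    g = 0
    for chrom in chroms:
        usable = len(genome[chrom]) - 2 * margin
        if per_chrom * (gene_span + margin) > usable:
            raise ValueError("chromosomes too short for the requested gene layout")
        for k in range(per_chrom):
            if g >= n_genes:
                break
            start = margin + k * (gene_span + margin)
            strand = "+" if g % 2 == 0 else "-"
            exons = [
                GenomicInterval(
                    chrom,
                    start + e * (exon_len + intron_len),
                    start + e * (exon_len + intron_len) + exon_len,
                    strand,
                )
                for e in range(exons_per_gene)
            ]
            genes[f"GENE{g + 1:03d}"] = exons
            g += 1
    return genes


def write_gtf(genes: Mapping[str, Sequence[GenomicInterval]], path: str | Path) -> None:
    """GTF with gene/transcript/exon lines (1-based inclusive on write)."""
    with open(path, "w") as fh:
        for gene_id, exons in genes.items():
            chrom = exons[0].chrom
            strand = exons[0].strand
            lo = min(e.start for e in exons) + 1
            hi = max(e.end for e in exons)
            attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.1"; gene_type "protein_coding";'
            fh.write(f"{chrom}\ttoy\tgene\t{lo}\t{hi}\t.\t{strand}\t.\t{attrs}\n")
            fh.write(f"{chrom}\ttoy\ttranscript\t{lo}\t{hi}\t.\t{strand}\t.\t{attrs}\n")
            for e in exons:
                fh.write(f"{chrom}\ttoy\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t{attrs}\n")


def _tx_order(exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    ordered = sorted(exons, key=lambda e: e.start)
    return list(reversed(ordered)) if ordered[0].strand == "-" else ordered


def transcript_sequence(
    genome: Mapping[str, str], exons: Sequence[GenomicInterval], first_exon: int = 0
) -> str:
    """Spliced transcript (transcript orientation) of exons[first_exon:]."""
    parts = []
    for e in _tx_order(exons)[first_exon:]:
        seq = genome[e.chrom][e.start : e.end]
        parts.append(reverse_complement(seq) if e.strand == "-" else seq)
    return "".join(parts)


# --- retrocopy planting -----------------------------------------------------


_L1_MOTIF = "GGAGGCCGAGGCAGGAGGATCGCTTGAGCCCAGGAGTTCGAGACCAGC"


def _l1_fragment(length: int, subfamily: str) -> str:
    # deterministic pseudo-L1: repeated motif tagged by subfamily hash
    reps = -(-length // len(_L1_MOTIF))
    return (_L1_MOTIF * reps)[:length]


@dataclass
class PlantedTruth:
    event: RetrocopyEvent
    insert_seq: str
    alt_chrom_seq: str
    insert_start: int  # start of insert cassette on the alt haplotype
    spliced_len: int


def retrocopy_insert_sequence(
    genome: Mapping[str, str], exons: Sequence[GenomicInterval], event: RetrocopyEvent
) -> str:
    spliced = transcript_sequence(genome, exons, event.first_exon)
    core = reverse_complement(spliced) if event.orientation == "-" else spliced
    insert = core + "A" * event.polyA_len
    if event.l1_co_insertion is not None:
        label, length = event.l1_co_insertion
        insert += _l1_fragment(length, label)
    return insert


def plant_retrocopy(
    genome: Mapping[str, str],
    annotation: Mapping[str, Sequence[GenomicInterval]],
    event: RetrocopyEvent,
) -> PlantedTruth:
    """Build the alternate haplotype carrying the event.

    The target site sequence of ``tsd_len`` bases starting at the insertion
    point is duplicated so it flanks the insert on both sides.
    """
    exons = annotation[event.parent_gene]
    insert = retrocopy_insert_sequence(genome, exons, event)
    chrom_seq = genome[event.insertion_site.chrom]
    s = event.insertion_site.start
    alt = chrom_seq[: s + event.tsd_len] + insert + chrom_seq[s:]
    spliced_len = len(insert) - event.polyA_len - (
        event.l1_co_insertion[1] if event.l1_co_insertion else 0
    )
    return PlantedTruth(
        event=event,
        insert_seq=insert,
        alt_chrom_seq=alt,
        insert_start=s + event.tsd_len,
        spliced_len=spliced_len,
    )


# --- exome (junction) read simulation ---------------------------------------


@dataclass
class WesSample:
    sample_id: str
    unmapped_reads: list[tuple[str, str]]  # (read_id, sequence)
    read_truth: dict[str, dict]  # read_id -> truth record
    planted_genes: set[str]


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode(), len(hits)


def simulate_wes(
    genome: Mapping[str, str],
    annotation: Mapping[str, Sequence[GenomicInterval]],
    events_by_sample: Mapping[str, Sequence[RetrocopyEvent]],
    coverage: float = 65.0,
    read_len: int = 76,
    error_rate: float = 0.001,
    seed: int = 0,
) -> dict[str, WesSample]:
    """Exome reads over each carrier's retrocopy transcript.

    Read starts are uniform over the spliced transcript at the requested
    depth; reads spanning an exon-exon boundary enter the sample's
    unmapped pool (with random strand and substitution errors), since they
    cannot map to the intron-containing reference. Reads interior to one
    exon map to the genome and are irrelevant to the junction path, so they
    are not materialized.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, WesSample] = {}
    for sample_id in sorted(events_by_sample):
        unmapped: list[tuple[str, str]] = []
        truth: dict[str, dict] = {}
        planted: set[str] = set()
        for ev_i, event in enumerate(events_by_sample[sample_id]):
            exons = annotation[event.parent_gene]
            tx = transcript_sequence(genome, exons, event.first_exon)
            exon_lens = [len(e) for e in _tx_order(exons)[event.first_exon :]]
            boundaries = list(np.cumsum(exon_lens)[:-1])
            n_reads = int(round(coverage * len(tx) / read_len))
            if not boundaries or n_reads == 0:
                continue
            planted.add(event.parent_gene)
            starts = rng.integers(0, len(tx) - read_len + 1, size=n_reads)
            for j, u in enumerate(starts):
                u = int(u)
                spanned = [b for b in boundaries if u < b < u + read_len]
                if not spanned:
                    continue
                frag = tx[u : u + read_len]
                frag, n_err = _mutate(frag, rng, error_rate)
                flipped = bool(rng.random() < 0.5)
                seq = reverse_complement(frag) if flipped else frag
                read_id = f"{sample_id}:{event.parent_gene}:{ev_i}:{j}"
                unmapped.append((read_id, seq))
                truth[read_id] = {
                    "gene_id": event.parent_gene,
                    "tx_start": u,
                    "n_errors": n_err,
                    "boundaries_spanned": spanned,
                    "flipped": flipped,
                    "first_exon": event.first_exon,
                }
        out[sample_id] = WesSample(
            sample_id=sample_id, unmapped_reads=unmapped, read_truth=truth, planted_genes=planted
        )
    return out


def verify_wes_reads(
    sample: WesSample,
    genome: Mapping[str, str],
    annotation: Mapping[str, Sequence[GenomicInterval]],
) -> bool:
    """Check every emitted read against its truth record.

    The read sequence must equal the recorded transcript substring up to
    exactly the recorded number of substitution errors.
    """
    for read_id, seq in sample.unmapped_reads:
        t = sample.read_truth[read_id]
        tx = transcript_sequence(genome, annotation[t["gene_id"]], t["first_exon"])
        expected = tx[t["tx_start"] : t["tx_start"] + len(seq)]
        observed = reverse_complement(seq) if t["flipped"] else seq
        mm = sum(a != b for a, b in zip(observed, expected))
        if mm != t["n_errors"]:
            return False
    return True


# --- whole-genome paired-end simulation --------------------------------------


def _map_insert_offset(
    offset: int,
    length: int,
    truth: PlantedTruth,
    annotation: Mapping[str, Sequence[GenomicInterval]],
) -> GenomicInterval | None:
    """Parent-gene coordinates of an insert-relative window, or None when
    the window leaves the spliced portion or crosses an exon boundary."""
    ev = truth.event
    S = truth.spliced_len
    if offset < 0 or offset + length > S:
        return None  # poly-A / L1 / outside
    if ev.orientation == "-":
        tx_lo = S - (offset + length)
    else:
        tx_lo = offset
    tx_hi = tx_lo + length
    exons = _tx_order(annotation[ev.parent_gene])[ev.first_exon :]
    cum = 0
    for e in exons:
        if tx_lo >= cum and tx_hi <= cum + len(e):
            rel_lo = tx_lo - cum
            if e.strand == "-":
                return GenomicInterval(e.chrom, e.end - (tx_hi - cum), e.end - rel_lo, e.strand)
            return GenomicInterval(e.chrom, e.start + rel_lo, e.start + rel_lo + length, e.strand)
        cum += len(e)
    return None


def simulate_wgs_pairs(
    genome: Mapping[str, str],
    annotation: Mapping[str, Sequence[GenomicInterval]],
    truths: Sequence[PlantedTruth],
    coverage: float = 7.4,
    read_len: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    seed: int = 0,
    mapq: int = 60,
) -> list[AlignmentRecord]:
    """Paired-end reads around each planted insertion on the alt haplotype.

    Fragments are drawn at the requested physical coverage over a window
    spanning the insertion; insert sizes are truncated-normal with a floor
    of 2x read length. A pair becomes an informative discordant pair when
    one read maps to the genomic flank and its mate lies within the spliced
    (exonic) part of the insert: the mate is emitted at its parent-gene
    coordinate. Mates in poly-A or L1 sequence are unplaceable and the pair
    is dropped, which starves one side of L1 co-insertion events.
    """
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    for t_i, truth in enumerate(truths):
        ev = truth.event
        chrom = ev.insertion_site.chrom
        K = len(truth.insert_seq)
        s_alt = truth.insert_start  # insert start on alt haplotype
        win_lo = max(0, s_alt - int(3 * insert_mean))
        win_hi = min(len(truth.alt_chrom_seq), s_alt + K + int(3 * insert_mean))
        n_frag = int(round(coverage * (win_hi - win_lo) / (2.0 * read_len)))
        for f in range(n_frag):
            isize = max(2 * read_len, int(round(rng.normal(insert_mean, insert_sd))))
            lo = int(rng.integers(win_lo, max(win_lo + 1, win_hi - isize)))
            r1 = (lo, lo + read_len, False)  # forward on alt
            r2 = (lo + isize - read_len, lo + isize, True)  # reverse on alt
            placed = []
            for (a_lo, a_hi, rev) in (r1, r2):
                if a_hi <= s_alt:
                    placed.append(("genome", GenomicInterval(chrom, a_lo, a_hi, "-" if rev else "+")))
                elif a_lo >= s_alt + K:
                    g_lo = a_lo - K - ev.tsd_len
                    placed.append(("genome", GenomicInterval(chrom, g_lo, g_lo + read_len, "-" if rev else "+")))
                else:
                    iv = _map_insert_offset(a_lo - s_alt, read_len, truth, annotation)
                    if iv is None:
                        placed.append(("lost", None))
                    else:
                        gene_minus = iv.strand == "-"
                        flips = int(rev) + int(ev.orientation == "-") + int(gene_minus)
                        strand = "-" if flips % 2 else "+"
                        placed.append(("gene", GenomicInterval(iv.chrom, iv.start, iv.end, strand)))
            kinds = {placed[0][0], placed[1][0]}
            if "lost" in kinds or kinds == {"genome"}:
                continue
            if kinds == {"gene"}:
                continue  # pair fully inside the insert: concordant within the copy
            read_id = f"wgs:{t_i}:{f}"
            for mate_i, (kind, iv) in enumerate(placed):
                mate_iv = placed[1 - mate_i][1]
                records.append(
                    AlignmentRecord(
                        read_id=read_id,
                        mapped=True,
                        interval=iv,
                        mapq=mapq,
                        mate_interval=mate_iv,
                        is_read1=(mate_i == 0),
                        cigar=[("M", read_len)],
                        n_mismatch=0,
                    )
                )
    return records


# --- cohort simulation -------------------------------------------------------


@dataclass
class SyntheticCohort:
    manifest: pd.DataFrame  # sample, population, superpopulation
    carrier_matrix: pd.DataFrame  # individuals x genes (bool)
    calls: list  # ParentGeneCall-like rows
    expression: pd.DataFrame  # genes x individuals


def default_cohort_design(
    genes: Sequence[str],
    n_per_pop: int = 10,
    base_freq: float = 0.1,
    private_superpop_genes: Mapping[str, str] | None = None,
    private_freq: float = 0.8,
    seed: int = 0,
) -> CohortDesign:
    """Design with a shared background frequency plus optional genes
    restricted to a single superpopulation at elevated frequency."""
    pops = all_populations()
    spmap = superpop_map()
    freq = pd.DataFrame(base_freq, index=list(genes), columns=pops, dtype=float)
    if private_superpop_genes:
        for gene, sp in private_superpop_genes.items():
            freq.loc[gene] = 0.0
            freq.loc[gene, [p for p in pops if spmap[p] == sp]] = private_freq
    return CohortDesign(
        populations=pops, superpop_map=spmap, n_per_pop=n_per_pop, gene_pop_freq=freq, seed=seed
    )


def simulate_cohort(
    design: CohortDesign,
    expression_effect: float = 0.0,
    n_background_genes: int = 0,
    seed: int | None = None,
) -> SyntheticCohort:
    """Draw a carrier matrix from the design's per-population frequencies.

    Expression is log-normal per gene; carriers of a gene get an additive
    shift of ``expression_effect`` (in units of the per-gene SD of the
    normal component). ``n_background_genes`` extra non-parent genes pad
    the expression table for genome-wide rank tests.
    """
    from .junction_caller import ParentGeneCall

    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = list(design.gene_pop_freq.index)
    samples, pops_col, sp_col = [], [], []
    for pop in design.populations:
        for i in range(design.n_per_pop):
            samples.append(f"{pop}_{i:03d}")
            pops_col.append(pop)
            sp_col.append(design.superpop_map[pop])
    manifest = pd.DataFrame({"sample": samples, "population": pops_col, "superpopulation": sp_col})
    carrier = pd.DataFrame(False, index=samples, columns=genes)
    calls = []
    for pop in design.populations:
        members = manifest.loc[manifest["population"] == pop, "sample"]
        for gene in genes:
            p = design.gene_pop_freq.loc[gene, pop]
            if p <= 0:
                continue
            draws = rng.random(len(members)) < p
            for sample, hit in zip(members, draws):
                if hit:
                    carrier.loc[sample, gene] = True
                    calls.append(
                        ParentGeneCall(
                            sample_id=sample, gene_id=gene,
                            supporting_junctions=[], population=pop,
                        )
                    )
    all_genes = genes + [f"BG{i:04d}" for i in range(n_background_genes)]
    base = rng.lognormal(mean=1.0, sigma=1.0, size=len(all_genes))
    noise = rng.normal(0.0, 1.0, size=(len(all_genes), len(samples)))
    expr = pd.DataFrame(
        base[:, None] + noise, index=all_genes, columns=samples
    )
    if expression_effect != 0.0:
        for gene in genes:
            mask = carrier[gene].to_numpy()
            expr.loc[gene, mask] = expr.loc[gene, mask] + expression_effect
    return SyntheticCohort(
        manifest=manifest, carrier_matrix=carrier, calls=calls, expression=expr
    )
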