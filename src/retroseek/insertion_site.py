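"""Insertion-site detection from discordant read pairs.

A retrocopy inserted far from its parent gene leaves a paired-end
signature: one mate maps inside the parent gene (it came from the inserted
copy) while the other maps to the genomic flank of the insertion point.
Pooled per population, the flank-mapping mates pile up on both sides of the
point — forward-strand reads to its left, reverse-strand reads to its
right. Average-linkage clustering of their 5' coordinates with a 500 bp
cutoff groups reads supporting the same event; a two-sided call needs at
least two reads on each side, and a single-sided call (interpreted as L1
co-insertion masking one flank) needs at least four reads on one side and
none on the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .io_formats import AlignmentRecord, GenomicInterval

DEFAULT_CUTOFF = 500
DEFAULT_MIN_MAPQ = 15
DEFAULT_MIN_DISTANCE = 1000


@dataclass(frozen=True)
class DiscordantPair:
    population: str
    gene_id: str
    anchor: GenomicInterval  # read inside the parent gene
    distal: GenomicInterval  # mate near the insertion point
    distal_strand: str
    mapq: int

    @property
    def distal_position(self) -> int:
        """5' mapped coordinate of the distal read."""
        return self.distal.start if self.distal_strand == "+" else self.distal.end


@dataclass
class ReadCluster:
    side: str  # "left" or "right"
    positions: list[int]
    chrom: str
    pairs: list[DiscordantPair] = field(default_factory=list)

    @property
    def inner_edge(self) -> int:
        """Coordinate of the cluster edge facing the insertion point."""
        return max(self.positions) if self.side == "left" else min(self.positions)

    @property
    def support(self) -> int:
        return len(self.positions)


@dataclass
class InsertionCall:
    gene_id: str
    site: GenomicInterval
    orientation: str
    left_support: int
    right_support: int
    call_type: str  # "two_sided" or "single_sided"
    populations: set[str] = field(default_factory=set)


def expected_support_distance(insert_size: float, read_length: float) -> float:
    """Expected distance between 5' coordinates of two same-side reads
    supporting one insertion point, under uniform read placement:
    (2(IS - RL) + 1) / 3.
    """
    return (2.0 * (insert_size - read_length) + 1.0) / 3.0


# --- discordant pair collection --------------------------------------------


def collect_discordant(
    alignments: Iterable[AlignmentRecord],
    parent_genes: Mapping[str, GenomicInterval],
    population: str = "",
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_distance: int = DEFAULT_MIN_DISTANCE,
) -> list[DiscordantPair]:
    """Pairs with one read in a parent gene and the mate on another
    chromosome or >= ``min_distance`` from the gene, both mapq >= ``min_mapq``.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        if rec.mapped and rec.interval is not None:
            by_read.setdefault(rec.read_id, []).append(rec)
    out: list[DiscordantPair] = []
    for read_id in sorted(by_read):
        recs = by_read[read_id]
        if len(recs) != 2:
            continue
        a, b = recs
        if min(a.mapq, b.mapq) < min_mapq:
            continue
        for anchor_rec, distal_rec in ((a, b), (b, a)):
            gene_hit = None
            for gene_id, gene_iv in parent_genes.items():
                if anchor_rec.interval.overlaps(gene_iv):
                    gene_hit = (gene_id, gene_iv)
                    break
            if gene_hit is None:
                continue
            gene_id, gene_iv = gene_hit
            distal_iv = distal_rec.interval
            if distal_iv.chrom == gene_iv.chrom and distal_iv.distance(gene_iv) < min_distance:
                continue
            out.append(
                DiscordantPair(
                    population=population,
                    gene_id=gene_id,
                    anchor=anchor_rec.interval,
                    distal=distal_iv,
                    distal_strand=distal_iv.strand,
                    mapq=min(a.mapq, b.mapq),
                )
            )
            break
    return out


# --- clustering -------------------------------------------------------------


def cluster_positions(
    positions: Sequence[int], cutoff: float = DEFAULT_CUTOFF, side: str = "left", chrom: str = ""
) -> list[ReadCluster]:
    """Average-linkage agglomeration of 1-D coordinates, stopping when the
    minimum inter-cluster average distance exceeds ``cutoff``.

    Returns clusters ordered by leftmost member; invariant to input order.
    """
    if len(positions) == 0:
        return []
    pos = sorted(positions)
    if len(pos) == 1:
        return [ReadCluster(side=side, positions=pos, chrom=chrom)]
    Z = linkage(np.asarray(pos, dtype=float).reshape(-1, 1), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    groups: dict[int, list[int]] = {}
    for p, lab in zip(pos, labels):
        groups.setdefault(lab, []).append(p)
    clusters = [ReadCluster(side=side, positions=sorted(g), chrom=chrom) for g in groups.values()]
    clusters.sort(key=lambda c: c.positions[0])
    return clusters


def cluster_pairs(
    pairs: Sequence[DiscordantPair], cutoff: float = DEFAULT_CUTOFF
) -> tuple[list[ReadCluster], list[ReadCluster]]:
    """Cluster one gene's discordant pairs on one chromosome by side."""
    left = [p for p in pairs if p.distal_strand == "+"]
    right = [p for p in pairs if p.distal_strand == "-"]
    results = []
    for side, group in (("left", left), ("right", right)):
        if not group:
            results.append([])
            continue
        chrom = group[0].distal.chrom
        clusters = cluster_positions([p.distal_position for p in group], cutoff, side, chrom)
        pos_to_cluster: dict[int, ReadCluster] = {}
        for cl in clusters:
            for p in cl.positions:
                pos_to_cluster[p] = cl
        for p in sorted(group, key=lambda p: p.distal_position):
            pos_to_cluster[p.distal_position].pairs.append(p)
        results.append(clusters)
    return results[0], results[1]


def _cluster_orientation(cluster: ReadCluster) -> str:
    """Infer retrocopy orientation from anchor-read strands.

    For a same-orientation ('+') insertion, left-flank distal reads pair
    with reverse-strand anchors in the parent gene and right-flank ones
    with forward-strand anchors; the mirrored pattern indicates '-'.
    """
    if not cluster.pairs:
        return "+"
    rev = sum(1 for p in cluster.pairs if p.anchor.strand == "-")
    frac_rev = rev / len(cluster.pairs)
    if cluster.side == "left":
        return "+" if frac_rev >= 0.5 else "-"
    return "+" if frac_rev < 0.5 else "-"


def _populations(clusters: Iterable[ReadCluster]) -> set[str]:
    pops = set()
    for cl in clusters:
        for p in cl.pairs:
            if p.population:
                pops.add(p.population)
    return pops


def call_sites(
    left_clusters: Sequence[ReadCluster],
    right_clusters: Sequence[ReadCluster],
    gene_id: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[InsertionCall], list[ReadCluster]]:
    """Pair left and right clusters into two-sided calls.

    A left cluster pairs with the nearest compatible right cluster whose
    inner edge lies within ``cutoff`` (overlap allowed: target-site
    duplication makes flank reads interleave). Both clusters need >= 2
    reads. Returns (calls, unpaired clusters) — the remainder feeds
    single-sided calling.
    """
    calls: list[InsertionCall] = []
    unpaired: list[ReadCluster] = []
    available = [c for c in right_clusters]
    for lc in sorted(left_clusters, key=lambda c: c.inner_edge):
        if lc.support < 2:
            unpaired.append(lc)
            continue
        best = None
        for rc in available:
            if rc.support < 2 or rc.chrom != lc.chrom:
                continue
            gap = abs(rc.inner_edge - lc.inner_edge)
            if gap > cutoff:
                continue
            if best is None or gap < abs(best.inner_edge - lc.inner_edge):
                best = rc
        if best is None:
            unpaired.append(lc)
            continue
        available.remove(best)
        lo = min(lc.inner_edge, best.inner_edge)
        hi = max(lc.inner_edge, best.inner_edge)
        site = GenomicInterval(lc.chrom, lo, max(hi, lo + 1))
        calls.append(
            InsertionCall(
                gene_id=gene_id,
                site=site,
                orientation=_cluster_orientation(lc),
                left_support=lc.support,
                right_support=best.support,
                call_type="two_sided",
                populations=_populations([lc, best]),
            )
        )
    unpaired.extend(c for c in available)
    return calls, unpaired


def call_single_sided(
    unpaired_clusters: Sequence[ReadCluster], gene_id: str, min_support: int = 4
) -> list[InsertionCall]:
    """Clusters with >= 4 reads and no mate-side cluster become
    single-sided calls (candidate L1 co-insertions)."""
    calls = []
    for cl in unpaired_clusters:
        if cl.support < min_support:
            continue
        lo, hi = min(cl.positions), max(cl.positions)
        site = GenomicInterval(cl.chrom, lo, max(hi, lo + 1))
        calls.append(
            InsertionCall(
                gene_id=gene_id,
                site=site,
                orientation=_cluster_orientation(cl),
                left_support=cl.support if cl.side == "left" else 0,
                right_support=cl.support if cl.side == "right" else 0,
                call_type="single_sided",
                populations=_populations([cl]),
            )
        )
    return calls


def call_insertions(
    pairs: Sequence[DiscordantPair], cutoff: float = DEFAULT_CUTOFF
) -> list[InsertionCall]:
    """Full per-population site calling over a set of discordant pairs."""
    calls: list[InsertionCall] = []
    keys = sorted({(p.gene_id, p.distal.chrom) for p in pairs})
    for gene_id, chrom in keys:
        group = [p for p in pairs if p.gene_id == gene_id and p.distal.chrom == chrom]
        left, right = cluster_pairs(group, cutoff)
        two_sided, unpaired = call_sites(left, right, gene_id, cutoff)
        calls.extend(two_sided)
        calls.extend(call_single_sided(unpaired, gene_id))
    return calls


# --- cross-population merging ----------------------------------------------


def _is_primary(chrom: str, primary_chroms: set[str] | None) -> bool:
    if primary_chroms is not None:
        return chrom in primary_chroms
    return "_" not in chrom  # alternative loci carry underscore-suffixed names


def merge_across_populations(
    calls: Sequence[InsertionCall],
    single_sided_distance: int = DEFAULT_CUTOFF,
    primary_chroms: set[str] | None = None,
) -> list[InsertionCall]:
    """Merge calls representing one event seen in several populations.

    Two-sided calls merge when gene, orientation and chromosome match and
    the site intervals overlap; single-sided calls merge when gene and
    orientation match and the sites lie within ``single_sided_distance``.
    Calls on alternative loci are excluded.
    """
    calls = [c for c in calls if _is_primary(c.site.chrom, primary_chroms)]
    merged: list[InsertionCall] = []
    for call_type in ("two_sided", "single_sided"):
        groups: dict[tuple, list[InsertionCall]] = {}
        for c in (c for c in calls if c.call_type == call_type):
            groups.setdefault((c.gene_id, c.orientation, c.site.chrom), []).append(c)
        for key in sorted(groups):
            members = sorted(groups[key], key=lambda c: (c.site.start, c.site.end))
            current: list[InsertionCall] = []
            for c in members:
                if current and _mergeable(current[-1], c, call_type, single_sided_distance):
                    current.append(c)
                else:
                    if current:
                        merged.append(_merge_group(current))
                    current = [c]
            if current:
                merged.append(_merge_group(current))
    merged.sort(key=lambda c: (c.site.chrom, c.site.start, c.gene_id))
    return merged


def _mergeable(a: InsertionCall, b: InsertionCall, call_type: str, dist: int) -> bool:
    if call_type == "two_sided":
        return a.site.overlaps(b.site)
    return a.site.distance(b.site) <= dist


def _merge_group(group: list[InsertionCall]) -> InsertionCall:
    if len(group) == 1:
        return group[0]
    lo = min(c.site.start for c in group)
    hi = max(c.site.end for c in group)
    pops: set[str] = set()
    for c in group:
        pops |= c.populations
    return InsertionCall(
        gene_id=group[0].gene_id,
        site=GenomicInterval(group[0].site.chrom, lo, hi),
        orientation=group[0].orientation,
        left_support=sum(c.left_support for c in group),
        right_support=sum(c.right_support for c in group),
        call_type=group[0].call_type,
        populations=pops,
    )


def calls_to_bed(calls: Sequence[InsertionCall]):
    """Insertion calls as a BED-like DataFrame."""
    import pandas as pd

    rows = [
        {
            "chrom": c.site.chrom,
            "start": c.site.start,
            "end": c.site.end,
            "name": f"{c.gene_id}|{c.call_type}|{c.orientation}",
            "support": c.left_support + c.right_support,
            "strand": c.orientation,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "support", "strand"])
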