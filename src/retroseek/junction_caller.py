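"""Score junction alignments, tune (d, r), call parent genes, estimate FDR.

The calling rule: a gene is reported as having a novel retroduplication in a
sample when at least two supported junctions are pairwise "non-overlapping"
(sharing no exon flank segment and having disjoint genomic footprints) and
at least one supported junction has >= 2 distinct supporting reads.

FDR control: calling parameters d (minimum bases on each side of the
junction) and r_max (maximum mismatch rate) are tuned by grid search to
maximize true-library calls subject to zero calls from every decoy library
in every sample. Observing zero decoy-driven false calls across n samples
bounds the per-sample false-call rate lambda through the Poisson model:
P(zero false calls everywhere) = exp(-lambda)^n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignmentRecord
from .junction_library import ExonJunction, JunctionLibrary

R_GRID = tuple(round(0.005 * i, 3) for i in range(11))  # 0.000 .. 0.050
D_GRID = tuple(range(1, 16))


@dataclass(frozen=True)
class JunctionHit:
    """One read-to-junction alignment with side lengths and mismatch rate."""

    read_id: str
    junction_id: str
    d1: int
    d2: int
    n_mismatch: int
    r: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("d1, d2 must be >= 0")


@dataclass(frozen=True)
class CallingParameters:
    d: int
    r_max: float

    def __post_init__(self) -> None:
        if not (1 <= self.d <= 15):
            raise ValueError("d must be in [1, 15]")
        if not (0.0 <= self.r_max <= 0.05):
            raise ValueError("r_max must be in [0.00, 0.05]")


@dataclass
class ParentGeneCall:
    sample_id: str
    gene_id: str
    supporting_junctions: list[tuple[str, int]]  # (junction_id, distinct read count)
    population: str = ""


@dataclass(frozen=True)
class FdrEstimate:
    confidence: float
    lambda_per_sample: float
    projected_false_calls: float
    n_samples: int


# --- scoring ----------------------------------------------------------------

_CONSUMES_REF = {"M", "D", "N", "=", "X"}
_ALIGNED = {"M", "=", "X"}


def score_hit(alignment: AlignmentRecord, junction: ExonJunction, sample_id: str = "") -> JunctionHit:
    """Split an alignment against a junction reference into side lengths.

    d1 counts aligned bases at reference positions before the junction
    offset, d2 those at or after it; soft/hard-clipped bases are excluded.
    """
    if not alignment.mapped or alignment.interval is None:
        raise ValueError("score_hit requires a mapped alignment")
    pos = alignment.interval.start
    offset = junction.junction_offset
    d1 = d2 = 0
    for op, length in alignment.cigar or [("M", len(alignment.sequence))]:
        if op in _ALIGNED:
            lo, hi = pos, pos + length
            d1 += max(0, min(hi, offset) - lo)
            d2 += max(0, hi - max(lo, offset))
        if op in _CONSUMES_REF:
            pos += length
    aligned = d1 + d2
    r = alignment.n_mismatch / aligned if aligned else 0.0
    return JunctionHit(
        read_id=alignment.read_id,
        junction_id=junction.junction_id,
        d1=d1,
        d2=d2,
        n_mismatch=alignment.n_mismatch,
        r=r,
        sample_id=sample_id,
    )


# --- a small ungapped seed-and-extend matcher for junction libraries --------


class JunctionMatcher:
    """Ungapped k-mer seeded matcher of short reads against a library.

    Stands in for an external aligner in the junction-evidence path: reads
    left unmapped by genome alignment are matched full-length against
    junction sequences, and the best placement (fewest mismatches, ties to
    lexicographically first junction then leftmost offset) is reported.
    """

    def __init__(self, library: JunctionLibrary, seed_len: int = 16, max_mismatch: int = 7):
        self.library = library
        self.seed_len = seed_len
        self.max_mismatch = max_mismatch
        self._by_id = library.by_id()
        self._index: dict[str, list[tuple[str, int]]] = {}
        for junc in library.junctions:
            seq = junc.sequence
            for p in range(0, len(seq) - seed_len + 1):
                self._index.setdefault(seq[p : p + seed_len], []).append((junc.junction_id, p))

    def match_read(self, read_id: str, seq: str, sample_id: str = "") -> JunctionHit | None:
        """Best placement over both read orientations."""
        from .io_formats import reverse_complement

        k = self.seed_len
        if len(seq) < k:
            return None
        best: tuple[int, str, int, str] | None = None
        for oriented in (seq, reverse_complement(seq)):
            candidates: set[tuple[str, int]] = set()
            for roff in range(0, len(oriented) - k + 1, max(1, k // 2)):
                for junction_id, jpos in self._index.get(oriented[roff : roff + k], ()):
                    start = jpos - roff
                    jseq = self._by_id[junction_id].sequence
                    if 0 <= start <= len(jseq) - len(oriented):
                        candidates.add((junction_id, start))
            for junction_id, start in candidates:
                jseq = self._by_id[junction_id].sequence
                mm = sum(a != b for a, b in zip(oriented, jseq[start : start + len(oriented)]))
                if mm > self.max_mismatch:
                    continue
                key = (mm, junction_id, start, oriented)
                if best is None or key[:3] < best[:3]:
                    best = key
        if best is None:
            return None
        mm, junction_id, start, seq = best
        junc = self._by_id[junction_id]
        from .io_formats import GenomicInterval

        rec = AlignmentRecord(
            read_id=read_id,
            mapped=True,
            interval=GenomicInterval(junction_id, start, start + len(seq), "+"),
            n_mismatch=mm,
            sequence=seq,
            cigar=[("M", len(seq))],
        )
        return score_hit(rec, junc, sample_id)

    def match_reads(self, reads: Iterable[tuple[str, str]], sample_id: str = "") -> list[JunctionHit]:
        hits = []
        for read_id, seq in reads:
            hit = self.match_read(read_id, seq, sample_id)
            if hit is not None:
                hits.append(hit)
        return hits


# --- filtering and calling --------------------------------------------------


def filter_hits(hits: Iterable[JunctionHit], params: CallingParameters) -> list[JunctionHit]:
    """Keep hits with min(d1, d2) >= d and r <= r_max (boundaries inclusive)."""
    eps = 1e-12  # guard against float representation of the r grid
    return [h for h in hits if min(h.d1, h.d2) >= params.d and h.r <= params.r_max + eps]


def _junctions_non_overlapping(a: ExonJunction, b: ExonJunction) -> bool:
    segs_a = (a.upstream.interval, a.downstream.interval)
    segs_b = (b.upstream.interval, b.downstream.interval)
    for iv_a in segs_a:
        for iv_b in segs_b:
            if iv_a == iv_b or iv_a.overlaps(iv_b):
                return False
    return True


def call_sample(
    filtered_hits: Iterable[JunctionHit],
    library: JunctionLibrary | Mapping[str, ExonJunction],
    sample_id: str = "",
    population: str = "",
) -> list[ParentGeneCall]:
    """Apply the two-junction rule to one sample's filtered hits."""
    by_id = library.by_id() if isinstance(library, JunctionLibrary) else dict(library)
    support: dict[str, dict[str, set[str]]] = {}  # gene -> junction -> read ids
    for hit in filtered_hits:
        junc = by_id.get(hit.junction_id)
        if junc is None:
            continue
        support.setdefault(junc.gene_id, {}).setdefault(hit.junction_id, set()).add(hit.read_id)
    calls = []
    for gene_id in sorted(support):
        junction_reads = support[gene_id]
        if len(junction_reads) < 2:
            continue
        if max(len(r) for r in junction_reads.values()) < 2:
            continue
        ids = sorted(junction_reads)
        if any(
            _junctions_non_overlapping(by_id[j1], by_id[j2])
            for j1, j2 in combinations(ids, 2)
        ):
            calls.append(
                ParentGeneCall(
                    sample_id=sample_id,
                    gene_id=gene_id,
                    supporting_junctions=[(j, len(junction_reads[j])) for j in ids],
                    population=population,
                )
            )
    return calls


# --- parameter tuning -------------------------------------------------------


def tune_parameters(
    true_hits_by_sample: Mapping[str, Sequence[JunctionHit]],
    decoy_hits_by_sample: Mapping[str, Mapping[int, Sequence[JunctionHit]]],
    true_library: JunctionLibrary,
    decoy_libraries: Sequence[JunctionLibrary],
) -> CallingParameters:
    """Grid-search (d, r_max) maximizing true calls under zero decoy calls.

    Feasible points produce zero calls from every decoy library in every
    sample; among feasible points the total true-library call count is
    maximized, with ties broken toward strictness (largest d, then smallest
    r_max). If nothing is feasible the strictest corner is returned.
    """
    decoys_by_e = {lib.e: lib for lib in decoy_libraries}
    best: tuple[int, int, float] | None = None  # (calls, d, -r) maximized
    best_params: CallingParameters | None = None
    for d in D_GRID:
        for r_max in R_GRID:
            params = CallingParameters(d=d, r_max=r_max)
            feasible = True
            for sample, per_lib in decoy_hits_by_sample.items():
                for e, hits in per_lib.items():
                    if call_sample(filter_hits(hits, params), decoys_by_e[e], sample):
                        feasible = False
                        break
                if not feasible:
                    break
            if not feasible:
                continue
            n_calls = sum(
                len(call_sample(filter_hits(hits, params), true_library, sample))
                for sample, hits in true_hits_by_sample.items()
            )
            key = (n_calls, d, -r_max)
            if best is None or key > best:
                best = key
                best_params = params
    if best_params is None:
        import logging

        logging.getLogger(__name__).warning(
            "no feasible (d, r_max) grid point: falling back to strictest corner"
        )
        return CallingParameters(d=15, r_max=0.0)
    return best_params


# --- FDR model --------------------------------------------------------------


def estimate_fdr(n_samples: int, confidence: float) -> FdrEstimate:
    """Poisson zero-decoy bound on the per-sample false-call rate.

    Zero false calls observed in every one of ``n_samples`` samples has
    probability exp(-lambda)^n under a per-sample Poisson(lambda) count;
    setting that equal to 1 - confidence gives
    lambda = -ln(1 - confidence) / n, and the projected number of false
    calls over the whole callset is lambda * n = -ln(1 - confidence).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    lam = -math.log(1.0 - confidence) / n_samples
    return FdrEstimate(
        confidence=confidence,
        lambda_per_sample=lam,
        projected_false_calls=lam * n_samples,
        n_samples=n_samples,
    )


def callset_fdr_bound(projected_false_calls: float, n_unique_parent_genes: int) -> float:
    """Upper bound on the callset FDR: projected false calls / unique genes."""
    if n_unique_parent_genes <= 0:
        raise ValueError("n_unique_parent_genes must be positive")
    if projected_false_calls < 0:
        raise ValueError("projected_false_calls must be >= 0")
    return projected_false_calls / n_unique_parent_genes


def calls_to_table(calls: Sequence[ParentGeneCall], library: JunctionLibrary):
    """Calls as a DataFrame mirroring the callset layout (one row per call).

    Chrom/Start/End give the junction location of the best-supported
    junction: the interval between the joined exon pair.
    """
    import pandas as pd

    by_id = library.by_id()
    rows = []
    for call in calls:
        best_j = max(call.supporting_junctions, key=lambda t: (t[1], t[0]))[0]
        junc = by_id[best_j]
        up, down = junc.upstream.interval, junc.downstream.interval
        lo, hi = sorted([up.start, up.end, down.start, down.end])[1:3]
        rows.append(
            {
                "Chrom": up.chrom,
                "Start": lo,
                "End": hi,
                "ParentGeneID": call.gene_id,
                "Sample": call.sample_id,
                "Population": call.population,
            }
        )
    return pd.DataFrame(rows, columns=["Chrom", "Start", "End", "ParentGeneID", "Sample", "Population"])
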