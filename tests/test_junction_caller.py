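import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroseek import (
    AlignmentRecord,
    CallingParameters,
    GenomicInterval,
    JunctionHit,
    JunctionMatcher,
    build_decoy_libraries,
    build_true_library,
    call_sample,
    callset_fdr_bound,
    estimate_fdr,
    filter_hits,
    score_hit,
    tune_parameters,
)
from retroseek.junction_caller import D_GRID, R_GRID


@pytest.fixture(scope="module")
def four_exon_setup():
    rng = np.random.default_rng(13)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), size=5000))}
    exons = [
        GenomicInterval("chr1", s, s + 250, "+") for s in (100, 800, 1500, 2200)
    ]
    genes = {"G1": exons}
    lib = build_true_library(genes, genome)
    return genome, genes, lib


def _hit(read_id, junction_id, d1=30, d2=30, nm=0, sample="s1"):
    total = d1 + d2
    return JunctionHit(read_id=read_id, junction_id=junction_id, d1=d1, d2=d2,
                       n_mismatch=nm, r=nm / total if total else 0.0, sample_id=sample)


class TestScoreHit:
    def _aln(self, start, cigar, nm=0, length=76):
        return AlignmentRecord(
            read_id="r", mapped=True,
            interval=GenomicInterval("J", start, start + length),
            cigar=cigar, n_mismatch=nm, sequence="A" * length,
        )

    def test_read_centered_on_junction(self, four_exon_setup):
        _, _, lib = four_exon_setup
        junc = lib.by_id()["J:G1:1-2"]  # offset 100, length 200
        hit = score_hit(self._aln(100 - 38, [("M", 76)]), junc)
        # oracle: manual cigar walk — 38 bases either side of offset 100
        assert (hit.d1, hit.d2, hit.r) == (38, 38, 0.0)

    def test_read_fully_upstream(self, four_exon_setup):
        _, _, lib = four_exon_setup
        junc = lib.by_id()["J:G1:1-2"]
        hit = score_hit(self._aln(10, [("M", 76)]), junc)
        assert hit.d2 == 0 and hit.d1 == 76

    def test_mismatch_rate(self, four_exon_setup):
        _, _, lib = four_exon_setup
        junc = lib.by_id()["J:G1:1-2"]
        hit = score_hit(self._aln(62, [("M", 76)], nm=2), junc)
        assert hit.r == pytest.approx(2 / 76)

    def test_clipped_bases_excluded(self, four_exon_setup):
        _, _, lib = four_exon_setup
        junc = lib.by_id()["J:G1:1-2"]
        aln = self._aln(90, [("S", 10), ("M", 60), ("S", 6)], length=60)
        aln.interval = GenomicInterval("J", 90, 150)
        hit = score_hit(aln, junc)
        assert (hit.d1, hit.d2) == (10, 50)


class TestFilterHits:
    def test_boundaries_inclusive(self):
        params = CallingParameters(d=6, r_max=0.05)
        rejected = _hit("a", "j", d1=5, d2=40)
        kept = JunctionHit(read_id="b", junction_id="j", d1=6, d2=40,
                           n_mismatch=0, r=0.05, sample_id="s")
        out = filter_hits([rejected, kept], params)
        assert out == [kept]

    @given(
        st.lists(
            st.tuples(st.integers(0, 40), st.integers(0, 40), st.integers(0, 5)),
            max_size=30,
        ),
        st.integers(1, 15),
        st.sampled_from(R_GRID),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_predicate(self, triples, d, r_max):
        hits = [
            _hit(f"r{i}", "j", d1=a, d2=b, nm=min(n, a + b))
            for i, (a, b, n) in enumerate(triples)
            if a + b > 0
        ]
        params = CallingParameters(d=d, r_max=r_max)
        expected = [h for h in hits if min(h.d1, h.d2) >= d and h.r <= r_max + 1e-12]
        assert filter_hits(hits, params) == expected


class TestCallSample:
    def test_two_disjoint_junctions_one_doubly_supported(self, four_exon_setup):
        _, _, lib = four_exon_setup
        hits = [
            _hit("r1", "J:G1:1-2"), _hit("r2", "J:G1:1-2"),
            _hit("r3", "J:G1:3-4"),
        ]
        calls = call_sample(hits, lib, "s1")
        assert [c.gene_id for c in calls] == ["G1"]

    def test_single_junction_not_called(self, four_exon_setup):
        _, _, lib = four_exon_setup
        hits = [_hit(f"r{i}", "J:G1:1-2") for i in range(5)]
        assert call_sample(hits, lib, "s1") == []

    def test_shared_segment_junctions_not_called(self, four_exon_setup):
        _, _, lib = four_exon_setup
        hits = [_hit("r1", "J:G1:1-2"), _hit("r2", "J:G1:1-3")]
        assert call_sample(hits, lib, "s1") == []

    def test_adjacent_junctions_on_long_middle_exon_are_non_overlapping(self, four_exon_setup):
        # (1,2) and (2,3) use opposite 100 bp flanks of the 250 bp middle exon
        _, _, lib = four_exon_setup
        hits = [_hit("r1", "J:G1:1-2"), _hit("r2", "J:G1:1-2"), _hit("r3", "J:G1:2-3")]
        assert [c.gene_id for c in call_sample(hits, lib, "s1")] == ["G1"]

    def test_duplicate_read_ids_counted_once(self, four_exon_setup):
        _, _, lib = four_exon_setup
        hits = [_hit("r1", "J:G1:1-2"), _hit("r1", "J:G1:1-2"), _hit("r2", "J:G1:3-4")]
        assert call_sample(hits, lib, "s1") == []  # no junction reaches 2 distinct reads

    def test_empty_input(self, four_exon_setup):
        _, _, lib = four_exon_setup
        assert call_sample([], lib, "s1") == []


class TestTuneParameters:
    def _oracle(self, true_hits, decoy_hits, true_lib, decoy_libs):
        """Independent exhaustive grid evaluation of the tuning rule."""
        decoys_by_e = {lib.e: lib for lib in decoy_libs}
        best = None
        for d in D_GRID:
            for r in R_GRID:
                params = CallingParameters(d=d, r_max=r)
                if any(
                    call_sample(filter_hits(h, params), decoys_by_e[e], s)
                    for s, per in decoy_hits.items()
                    for e, h in per.items()
                ):
                    continue
                n = sum(
                    len(call_sample(filter_hits(h, params), true_lib, s))
                    for s, h in true_hits.items()
                )
                key = (n, d, -r)
                if best is None or key > best[0]:
                    best = (key, params)
        return best[1] if best else CallingParameters(d=15, r_max=0.0)

    def test_matches_exhaustive_grid_oracle(self, four_exon_setup):
        genome, genes, lib = four_exon_setup
        decoys = build_decoy_libraries(genes, genome)
        rng = np.random.default_rng(5)
        true_hits = {
            "s1": [
                _hit(f"r{i}", jid, d1=int(rng.integers(1, 40)), d2=int(rng.integers(1, 40)),
                     nm=int(rng.integers(0, 3)))
                for i in range(30)
                for jid in [rng.choice(["J:G1:1-2", "J:G1:3-4", "J:G1:2-4"])]
            ]
        }
        decoy_hits = {
            "s1": {
                e: [
                    _hit(f"d{e}{i}", f"D{e}:G1:1-2", d1=20, d2=20, nm=int(rng.integers(0, 4)))
                    for i in range(3)
                ]
                for e in (1, 2, 3, 6, 12)
            }
        }
        tuned = tune_parameters(true_hits, decoy_hits, lib, decoys)
        assert tuned == self._oracle(true_hits, decoy_hits, lib, decoys)

    def test_planted_borderline_decoy_call_forces_stricter_r(self, four_exon_setup):
        genome, genes, lib = four_exon_setup
        decoys = build_decoy_libraries(genes, genome)
        e1 = decoys[0]
        # decoy call only possible at r_max = 0.05 (r = 3/60 exactly)
        decoy_hits = {
            "s1": {
                1: [
                    _hit("x1", "D1:G1:1-2", d1=30, d2=30, nm=3),
                    _hit("x2", "D1:G1:1-2", d1=30, d2=30, nm=3),
                    _hit("x3", "D1:G1:3-4", d1=30, d2=30, nm=3),
                ]
            }
        }
        true_hits = {"s1": [_hit("t1", "J:G1:1-2"), _hit("t2", "J:G1:1-2"), _hit("t3", "J:G1:3-4")]}
        tuned = tune_parameters(true_hits, decoy_hits, lib, decoys)
        assert tuned.r_max < 0.05

    def test_invariant_to_sample_ordering(self, four_exon_setup):
        genome, genes, lib = four_exon_setup
        decoys = build_decoy_libraries(genes, genome)
        hits_a = [_hit("r1", "J:G1:1-2", nm=1), _hit("r2", "J:G1:1-2"), _hit("r3", "J:G1:3-4")]
        hits_b = [_hit("q1", "J:G1:2-3", nm=2), _hit("q2", "J:G1:2-3"), _hit("q3", "J:G1:1-4", d1=8, d2=8)]
        fwd = tune_parameters({"a": hits_a, "b": hits_b}, {"a": {}, "b": {}}, lib, decoys)
        rev = tune_parameters({"b": hits_b, "a": hits_a}, {"b": {}, "a": {}}, lib, decoys)
        assert fwd == rev

    def test_monotonicity_of_call_counts(self, four_exon_setup):
        """Raising d or lowering r_max never increases the number of calls."""
        _, _, lib = four_exon_setup
        rng = np.random.default_rng(17)
        hits = [
            _hit(f"r{i}", jid, d1=int(rng.integers(1, 40)), d2=int(rng.integers(1, 40)),
                 nm=int(rng.integers(0, 4)))
            for i in range(60)
            for jid in [rng.choice(list(lib.by_id()))]
        ]
        counts = np.array([
            [len(call_sample(filter_hits(hits, CallingParameters(d=d, r_max=r)), lib, "s")) for r in R_GRID]
            for d in D_GRID
        ])
        assert (np.diff(counts, axis=0) <= 0).all()  # d up -> calls down
        assert (np.diff(counts, axis=1) >= 0).all()  # r up -> calls up


class TestFdrModel:
    def test_cohort_scale_lambda_and_projection(self):
        est = estimate_fdr(2533, 0.95)
        assert est.lambda_per_sample == pytest.approx(1.2e-3, rel=0.02)
        assert est.projected_false_calls == pytest.approx(3.0, rel=0.01)

    def test_closed_form_identity(self):
        est = estimate_fdr(1, 1 - math.exp(-1))
        assert est.lambda_per_sample == pytest.approx(1.0)

    def test_projection_independent_of_sample_count(self):
        for n in (10, 100, 2533):
            est = estimate_fdr(n, 0.95)
            assert est.lambda_per_sample * n == pytest.approx(-math.log(0.05))

    def test_callset_bound(self):
        assert callset_fdr_bound(3.0, 503) == pytest.approx(0.00596, abs=1e-4)
        assert callset_fdr_bound(0.0, 10) == 0.0
        assert callset_fdr_bound(-math.log(0.01), 503) < 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_fdr(0, 0.95)
        with pytest.raises(ValueError):
            estimate_fdr(10, 1.0)
        with pytest.raises(ValueError):
            callset_fdr_bound(1.0, 0)


class TestMatcher:
    def test_junction_spanning_read_scored_with_true_side_lengths(self, four_exon_setup):
        genome, _, lib = four_exon_setup
        junc = lib.by_id()["J:G1:2-3"]
        off = junc.junction_offset
        read = junc.sequence[off - 30 : off + 46]
        hit = JunctionMatcher(lib).match_read("r1", read)
        assert hit is not None
        assert (hit.d1, hit.d2, hit.n_mismatch) == (30, 46, 0)

    def test_reverse_complement_read_matched(self, four_exon_setup):
        from retroseek.io_formats import reverse_complement

        _, _, lib = four_exon_setup
        junc = lib.by_id()["J:G1:1-2"]
        off = junc.junction_offset
        read = reverse_complement(junc.sequence[off - 38 : off + 38])
        hit = JunctionMatcher(lib).match_read("r1", read)
        assert hit is not None and (hit.d1, hit.d2) == (38, 38)

    def test_unrelated_read_unmatched(self, four_exon_setup):
        _, _, lib = four_exon_setup
        assert JunctionMatcher(lib).match_read("r", "ACGT" * 19) is None
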