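# retroseek

Discovery and population-genetic analysis of **novel retroduplications**
(retrocopies / polymorphic processed pseudogenes): gene copies created when
an mRNA is reverse-transcribed by the L1 machinery and inserted back into
the genome. A retrocopy is intron-less, usually poly-A tailed, flanked by a
target-site duplication, and lies far from its parent gene — features that
leave two distinctive short-read signatures this package exploits:

1. **Exon–exon junction evidence (exome data).** Reads from a retrocopy's
   interior cross spliced exon boundaries and therefore fail to map to the
   intron-containing reference. `retroseek` builds a library of candidate
   junction sequences (all ordered exon pairs per gene, 100 bp flanks) and
   realigns unmapped reads against it. A read supports a junction when it
   covers at least *d* bases on each side with mismatch rate at most *r*;
   a gene is called in a sample when two non-overlapping junctions are
   supported and one has ≥ 2 distinct reads. *(d, r)* are tuned
   automatically — maximize true-library calls subject to **zero** calls
   from five decoy libraries built from coordinate-shifted (fake) exons
   (shifts e ∈ {1, 2, 3, 6, 12}). Observing zero decoy-driven calls across
   *n* samples bounds the per-sample false-call rate λ via the Poisson
   model exp(−λ)ⁿ = 1 − confidence.
2. **Discordant read pairs (whole-genome data).** At the insertion point,
   one mate maps into the parent gene while the other maps to the genomic
   flank. Flank-read 5′ coordinates are clustered by average linkage with a
   500 bp cutoff (the expected same-event read separation is
   (2(IS−RL)+1)/3 ≈ 134 bp for 300 bp inserts and 100 bp reads); two-sided
   calls need ≥ 2 reads per side, and one-sided clusters with ≥ 4 reads are
   called as candidate L1 co-insertions.

Downstream analyses: per-gene carrier-frequency matrices; a fixation-index
statistic F_ST = [p(1−p) − Σᵢ cᵢ pᵢ(1−pᵢ)]/[p(1−p)] over superpopulations
with label-shuffling permutation tests (BH-adjusted); population trees
(Manhattan distance, average linkage) with ordinary-bootstrap (BP) and
multiscale-bootstrap approximately-unbiased (AU) cluster support;
expression association (rank-sum per gene, Fisher omnibus, signed-rank
cross-check, genome-wide expression-rank test); permutation enrichment of
insertion sites against genomic tracks (gap-excluding same-chromosome
shuffles); and a simulation of how an alt-allele-carrying retrocopy erodes
SNP genotyping in its parent gene.

A first-class synthetic-data module makes every stage testable offline:
toy genomes, multi-exon genes, planted retrocopy alleles (5′ truncation,
poly-A, TSD, L1 co-insertion), truth-consistent exome and whole-genome
reads, and multi-population carrier cohorts.

## Worked example

```python
import numpy as np
from retroseek import GenomicInterval, collect_discordant, call_insertions, estimate_fdr
from retroseek import synthetic_data as sd
from retroseek.pipeline import run_junction_discovery

genome, gaps = sd.make_genome(seed=42, n_chrom=2, chrom_len=400_000)
genes = sd.make_annotation(genome, n_genes=20, seed=42, margin=8000)

event = sd.RetrocopyEvent(
    parent_gene="GENE001", first_exon=0,
    insertion_site=GenomicInterval("chr2", 300_000, 300_001), tsd_len=12,
)
result = run_junction_discovery(genome, genes, {"NA001": [event]}, coverage=65, seed=1)
print("tuned parameters:", result.params)
print("calls:", [c.gene_id for c in result.calls_by_sample["NA001"]])
print("decoy-library calls:", result.decoy_calls)

truth = sd.plant_retrocopy(genome, genes, event)
reads = sd.simulate_wgs_pairs(genome, genes, [truth], coverage=148, seed=2)
spans = {g: GenomicInterval(e[0].chrom, min(x.start for x in e), max(x.end for x in e))
         for g, e in genes.items()}
sites = call_insertions(collect_discordant(reads, spans, population="YRI"))
for s in sites:
    print(f"{s.call_type} insertion of {s.gene_id} at {s.site.chrom}:{s.site.start}-{s.site.end} "
          f"({s.left_support}+{s.right_support} reads)")

est = estimate_fdr(n_samples=2533, confidence=0.95)
print(f"per-sample false-call rate: {est.lambda_per_sample:.2e}")
print(f"projected false calls: {est.projected_false_calls:.1f}")
```

Output:

```
tuned parameters: CallingParameters(d=15, r_max=0.0)
calls: ['GENE001']
decoy-library calls: 0
two_sided insertion of GENE001 at chr2:299912-300100 (73+53 reads)
per-sample false-call rate: 1.18e-03
projected false calls: 3.0
```

The planted retrocopy of `GENE001` is recovered from exome junction reads
with the strictest feasible calling parameters and zero decoy calls; its
insertion site is localized to a ~190 bp window bracketing the planted
point (chr2:300,000) with two-sided discordant support. At the 2,533-sample
scale, zero observed decoy calls bound the per-sample false-call rate at
1.18 × 10⁻³ (95% confidence), i.e. about 3 projected false calls over the
whole callset.

A CLI mirrors the main stages: `retroseek call` (junction calling from a
SAM of unmapped exome reads), `retroseek insertions` (site detection from
pooled WGS SAM), `retroseek erode` (genotyping-erosion curves).

## Layout

- `retroseek.io_formats` — intervals/alignments plus GTF/GFF3, FASTA, SAM,
  BED, TSV readers and writers (0-based half-open internally).
- `retroseek.junction_library` — true and decoy exon-junction libraries.
- `retroseek.junction_caller` — hit scoring, (d, r) tuning, two-junction
  calling rule, Poisson zero-decoy FDR model, built-in k-mer matcher.
- `retroseek.insertion_site` — discordant-pair collection, average-linkage
  clustering, two-/single-sided calls, cross-population merging.
- `retroseek.popgen` — frequency matrix, F_ST permutation test, trees with
  BP/AU support, private-superpopulation fraction.
- `retroseek.association` — eQTL-style rank tests, Fisher omnibus,
  expression-rank analysis.
- `retroseek.enrichment` — gap-excluding shuffles, overlap statistics,
  aggregation profiles, retrodeletion overlap.
- `retroseek.snp_erosion` — pileup contamination and genotype-call model.
- `retroseek.synthetic_data` — genomes, annotations, planted events, read
  simulators, cohort generator.
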