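# Methods

## Problem and model

A retroduplication (retrocopy) is a gene copy produced by reverse
transcription of a spliced mRNA and reinsertion into the genome, normally
by the L1 retrotransposition machinery. Relative to the reference genome a
*novel* retrocopy is an insertion allele; it is intron-less, frequently 5′
truncated, carries a poly-A tail and a short target-site duplication
(TSD), and may be co-inserted with an L1 fragment. `retroseek` detects
such alleles from short-read data and quantifies their population
distribution.

### Junction evidence and decoy-based FDR control

The true junction library joins, for every gene and every ordered exon
pair (i < j in transcription order), the last ≤ 100 bases of exon i with
the first ≤ 100 bases of exon j, in transcript orientation (minus-strand
genes reverse-complemented). Non-adjacent pairs are included because
retrocopies may be truncated or skip exons; exons shorter than 100 bp
contribute their full length; junctions identical in sequence (duplicate
exon structures) are deduplicated. Exon pooling is done at the gene level
over the union of protein-coding exons across transcripts — order within
the gene is enforced, adjacency is not.

Reads left unmapped by genome alignment are matched against the junction
libraries. A hit is summarized by d1/d2 (aligned bases on either side of
the junction offset, clipped bases excluded) and mismatch rate
r = mismatches/(d1+d2). A hit passes when min(d1, d2) ≥ d and r ≤ r_max,
both boundaries inclusive. A gene is called in a sample when (a) at least
two supported junctions are pairwise non-overlapping — sharing no exon
flank segment and having disjoint genomic footprints; the flank, not the
whole exon, is the unit of sharing, so junctions (1,2) and (2,3) are
non-overlapping whenever the middle exon exceeds 200 bp — and (b) at least
one junction has ≥ 2 distinct supporting read ids.

Five decoy libraries apply the identical construction to exons shifted
inward by e ∈ {1, 2, 3, 6, 12} bases on both sides; shifted exons of
non-positive length are dropped. A read arising from a real junction can
seed into a decoy junction through the shared exon interior, but its bases
near the shifted boundary mismatch, so the (d, r) filters remove it —
conversely, any *call* assembled from decoy hits is a known false
positive. The calling parameters are tuned by full grid search
(d ∈ {1..15}, r_max ∈ {0, 0.005, …, 0.05}): feasible points yield zero
decoy-library calls in every sample; among feasible points the
true-library call total is maximized; ties break toward strictness
(largest d, then smallest r_max). The r-grid step of 0.005 is the coarsest
step that distinguishes single-mismatch increments on ~76 bp reads. If no
grid point is feasible the strictest corner (15, 0) is returned with a
warning.

With zero decoy calls observed in each of n samples and a per-sample
Poisson(λ) false-call count, P(no false call anywhere) = exp(−λ)ⁿ.
Setting this to 1 − confidence gives λ = −ln(1 − confidence)/n and a
projected −ln(1 − confidence) false calls over the callset; dividing by
the number of unique called parent genes bounds the callset FDR. The
implementation follows this closed form exactly; note that at 99%
confidence it gives λ = −ln(0.01)/n (≈ 1.8 × 10⁻³ for n = 2533), and the
projected count −ln(0.01) ≈ 4.6.

The package ships a small ungapped k-mer seed-and-extend matcher
(16-mer seeds, both read orientations, best placement by mismatch count
with deterministic ties) for aligning reads to junction libraries. It is a
full implementation of the ungapped matching problem on ≤ 200 bp
references, suitable because junction references are short and the scoring
needs exact d1/d2/mismatch accounting; SAM input from any external aligner
is equally accepted through `io_formats.read_sam` + `score_hit`.

### Insertion sites from discordant pairs

Pairs with both mates mapped at mapq ≥ 15, one mate inside a called parent
gene and the other on a different chromosome or ≥ 1 kb from the gene, are
collected per population (low-coverage genomes are pooled by population).
The flank-side ("distal") read's 5′ coordinate is the clustering position;
forward-strand distal reads form the left flank of a candidate insertion,
reverse-strand reads the right flank. Positions are clustered by
agglomerative average linkage, stopping when the minimum inter-cluster
mean distance exceeds 500 bp (scipy's average-linkage implementation; a
brute-force agglomeration oracle verifies equality in tests). The cutoff
is motivated by the expected separation of two same-event reads under
uniform read placement, (2(IS−RL)+1)/3 — about 134 bp for IS = 300,
RL = 100 — plus insert-size dispersion and TSD slack. The formula is
validated only against the package's own uniform-placement model.

A left and a right cluster pair into a two-sided call when both have ≥ 2
reads and their inner edges lie within the cutoff (overlap allowed — TSDs
make flank reads interleave); pairing is nearest-first and deterministic.
Unpaired clusters with ≥ 4 reads become single-sided calls, interpreted as
L1 co-insertion masking one flank (the co-inserted L1 is repetitive, so
mates landing in it cannot be anchored). Calls merge across populations
when gene, orientation and chromosome match and sites overlap (two-sided)
or lie within 500 bp (single-sided); alternative loci (underscore-suffixed
chromosome names, or anything outside a user-supplied primary set) are
excluded.

Orientation of the inserted copy is not defined by the flank geometry
alone; the adopted rule reads it from anchor-read strands (left-flank
distal reads pairing with reverse-strand anchors ⇒ '+', mirrored on the
right). The simulator emits strands under the same geometry, so the
convention is self-consistent; on real data it should be treated as a
heuristic.

## Population-genetic statistics

The frequency matrix A (M genes × N populations) holds the fraction of a
population's individuals carrying each retroduplication. Per gene,
F_ST = [p(1−p) − Σᵢ cᵢ pᵢ(1−pᵢ)]/[p(1−p)] over the five superpopulations,
with cᵢ the superpopulation share of individuals and p = Σ cᵢ pᵢ; by
concavity of x(1−x) the statistic lies in [0, 1], and it is defined as 0
when p(1−p) = 0 (no variation ⇒ no differentiation). Significance comes
from shuffling individual labels across the whole cohort (population sizes
preserved by construction), one-tailed empirical p = (r+1)/(n+1), BH
adjustment across genes. The +1 correction is standard conservative
permutation practice; note it floors attainable adjusted p-values at
permutation granularity times the BH factor.

Population trees use Manhattan distance between frequency columns and
average-linkage clustering. BP support for each internal clade is the
fraction of gene-row bootstrap replicates whose tree contains the same
leaf set. AU support comes from multiscale bootstrap: for scale ratios
ρ ∈ {0.5 … 1.4} (ten values), ⌈ρM⌉ rows are resampled; the profile
z(ρ) = Φ⁻¹(1 − BP(ρ)) is fit to v√ρ + c/√ρ by weighted least squares with
weights n·φ(z)²/(BP(1−BP)), and AU = 1 − Φ(v − c). When c = 0 this reduces
to AU = BP at ρ = 1 exactly (a test asserts it). Clades with degenerate BP
(0 or 1) at more than half the scales fall back to BP at the scale closest
to 1. A gene is "private" to a superpopulation when its carriers all lie
in one superpopulation; the reported fraction is over genes with any
carrier.

## Association tests

Within each population (to avoid stratification confounding): per parent
gene, carriers vs non-carriers are compared by two-sided Wilcoxon rank-sum
(exact enumeration for group sizes ≤ 10, tie-corrected normal
approximation otherwise; the switch point is fixed for reproducibility of
small fixtures), BH across genes, and Fisher's combined test
(X² = −2Σ ln pᵢ vs χ²(2k)) on the unadjusted p-values as the omnibus. A
two-sided Wilcoxon signed-rank test on paired per-gene group medians
cross-checks the omnibus. Fisher's method assumes independent tests; it is
applied without correlation correction, a documented limitation. The
genome-wide test ranks each parent gene's median expression among all G
genes' medians: p = #{medians ≥ parent}/(G+1), Fisher-combined.
Zero-variance genes are excluded with a log entry.

## Enrichment and profiles

Sites are widened about their midpoints to 500 bp (feature tracks) or
1,000 bp (genomic-element tracks) so heterogeneous location precision
cannot drive overlap statistics. The null re-places each site uniformly on
its own chromosome outside assembly gaps, preserving length; placement is
exact (valid start positions enumerated per gap-free segment, segment
chosen with probability proportional to its count of valid starts — no
rejection loop), so shuffled length distributions equal the observed one
by construction. Statistics: partial overlap (elements touched by ≥ 1 bp),
base overlap, and site-in-region count. Enrichment is observed/null-mean
(log2-reported); empirical p is the smaller of the two (r+1)/(n+1) tails;
Bonferroni corrects across the tracks of one invocation. Aggregation
profiles sum base overlap in 200 bp bins across ±flank windows at site
midpoints, smooth with a 10-bin moving average, and normalize by the mean
of the first and last 20 bins (floored at a configurable ε for sparse
tracks). Retrodeletions are deletion calls whose span is ≥ 50% covered by
a reference processed pseudogene; all qualifying (deletion, pseudogene)
pairs are reported and callers count distinct deletions for event totals.

## SNP genotyping erosion

An alt-allele-carrying retrocopy adds cross-mapping chromosomes to the
parent-locus pileup: a true hom-ref individual with one alt copy has
expected alt fraction 1/3, read by a diploid binomial genotyper
(alt probabilities {e, ½, 1−e}, uniform prior, quality = log10 likelihood
ratio of best to second-best) as heterozygous. Because depth sharpens the
likelihood around the contaminated fraction, the miscall rate *increases*
with depth — the qualitative claim the module's tests assert (it exceeds
0.99 by 80× with 10,000 replicates). Both homozygous genotypes erode with
a single cross-allele copy; a true heterozygote moves only to fraction
2/3, which remains likelihood-closest to het for realistic error rates, so
its erosion requires several copies plus elevated error — a property of
the declared model, stated here rather than hidden. All retrocopy reads
are assumed to cross-map (worst case); a mappability fraction relaxes
this.

## Synthetic data: what it emulates and what it does not

The generator produces uniform-base genomes (GC ≈ 0.5) with N-gap
intervals, evenly spaced multi-exon genes on alternating strands, and
planted retrocopy alleles with the full event anatomy (5′ truncation as a
transcript suffix, poly-A, TSD duplication of the target site, optional
L1 fragment). Exome simulation draws read starts uniformly over each
carrier's retrocopy transcript at the configured depth (defaults 65×,
76 bp, matching high-coverage exome practice) and materializes only
junction-spanning reads into the unmapped pool — reads interior to one
exon would map to the genome and never reach the junction matcher, so
this shortcut is exact for the junction path. Whole-genome simulation
(defaults 7.4×, 100 bp, 300 ± 30 bp inserts truncated at 2× read length)
draws fragments over a window spanning each insertion on the alternate
haplotype and emits truth-consistent coordinates; mates landing in poly-A
or L1 sequence are treated as unplaceable.

Not emulated: a realistic repeat landscape and the resulting mapping
ambiguity, indel/quality error profiles (substitutions only), reference
processed pseudogenes, and real population history (carrier matrices are
independent Bernoulli draws per individual at configured frequencies).
Passing tests therefore demonstrate correctness of the calling logic,
calibration of the statistics, and internal consistency of the geometry —
not performance under real-genome mappability artifacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the package's
own defaults: the end-to-end cohort uses 26 populations × 2 exomes with 20
genes and two planted events per sample at 65×; insertion-site checks pool
the equivalent of 20 genomes at 7.4× (148× local coverage); tree-support
checks use 200 informative genes × 1,000 bootstrap replicates; null
calibrations use 200–300 genes with 300 permutations against 99% DKW
bands; erosion curves use 10,000 replicates per depth. Random streams are
`numpy.random.default_rng` instances seeded per analysis; all public
entry points accept explicit seeds and are reproducible bit-for-bit under
a fixed seed. Average-linkage ties break toward the leftmost cluster;
empty inputs return empty outputs rather than raising throughout the
calling path.

Known limitations: junction calling cannot separate a full-length
retrocopy of a 3-exon gene with a short (< 200 bp) middle exon from a
single-junction artifact (the two junctions share flank footprints, so
the non-overlap rule vetoes the call); orientation inference for insertion
calls is heuristic; Fisher omnibus ignores inter-gene correlation; the FDR
model assumes a uniform per-sample false-call rate.
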