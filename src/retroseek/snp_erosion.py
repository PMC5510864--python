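"""SNP genotyping erosion inside retroduplication parent genes.

A retrocopy is a near-identical second copy of its parent gene's exons:
short reads derived from it cross-map back to the parent locus. If the
copy carries the alternative allele at a SNP position, the pileup at the
parent becomes a three-(or more-)chromosome mixture whose allele fraction
matches no diploid genotype — e.g. a true hom-ref individual with one
alt-carrying retrocopy shows an alt fraction of 1/3, which a diploid
caller reads as heterozygous. Deeper sequencing measures the contaminated
fraction more precisely, so the miscall becomes more confident: genotyping
quality deteriorates as depth grows. This module realizes that mechanism
as a simple binomial pileup-and-call simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOTYPES = ("RR", "RA", "AA")
_ALT_DOSE = {"RR": 0, "RA": 1, "AA": 2}


@dataclass(frozen=True)
class ErosionScenario:
    true_genotype: str  # RR / RA / AA
    retrocopy_allele: str  # R / A
    retrocopy_copies: int = 1
    depth: int = 30
    error_rate: float = 0.01
    mappability: float = 1.0  # fraction of retrocopy reads cross-mapping back
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_genotype not in GENOTYPES:
            raise ValueError("true_genotype must be RR, RA or AA")
        if self.retrocopy_allele not in ("R", "A"):
            raise ValueError("retrocopy_allele must be R or A")
        if self.retrocopy_copies < 0:
            raise ValueError("retrocopy_copies must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")

    @property
    def alt_fraction(self) -> float:
        """Expected alt-read fraction of the contaminated pileup (pre-error)."""
        parent_alt = _ALT_DOSE[self.true_genotype]
        retro_alt = self.retrocopy_copies * (1 if self.retrocopy_allele == "A" else 0)
        n_chrom = 2 + self.retrocopy_copies * self.mappability
        return (parent_alt + retro_alt * self.mappability) / n_chrom


def simulate_pileup(scenario: ErosionScenario, rng: np.random.Generator | None = None) -> tuple[int, int]:
    """Draw ``depth`` reads from the pooled allele mixture; sequencing error
    flips each read's allele with ``error_rate``. Returns (ref, alt) counts."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    f_alt = scenario.alt_fraction
    p_alt = f_alt * (1 - scenario.error_rate) + (1 - f_alt) * scenario.error_rate
    alt = int(rng.binomial(scenario.depth, p_alt))
    return scenario.depth - alt, alt


def genotype_call(ref_count: int, alt_count: int, error_rate: float = 0.01) -> tuple[str, float]:
    """Maximum-likelihood diploid genotype with a uniform prior.

    Alt-read probabilities are {e, 1/2, 1-e} for {RR, RA, AA}; the call is
    the argmax of the binomial likelihood and quality is the log10 ratio of
    best to second-best likelihood.
    """
    n = ref_count + alt_count
    if n < 1:
        raise ValueError("need at least one read")
    e = max(error_rate, 1e-12)
    logliks = {}
    for gt, p_alt in zip(GENOTYPES, (e, 0.5, 1.0 - e)):
        logliks[gt] = alt_count * math.log(p_alt) + ref_count * math.log(1.0 - p_alt)
    ordered = sorted(GENOTYPES, key=lambda g: logliks[g], reverse=True)
    quality = (logliks[ordered[0]] - logliks[ordered[1]]) / math.log(10.0)
    return ordered[0], quality


def erosion_curve(
    true_genotype: str = "RR",
    retrocopy_allele: str = "A",
    retrocopy_copies: int = 1,
    depths: tuple[int, ...] = (5, 10, 20, 40, 80),
    n_reps: int = 10000,
    error_rate: float = 0.01,
    mappability: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Miscall rate and mean genotype quality across a depth grid.

    Each replicate simulates one pileup and calls the genotype; a miscall
    is any call differing from the true parent genotype.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        scenario = ErosionScenario(
            true_genotype=true_genotype,
            retrocopy_allele=retrocopy_allele,
            retrocopy_copies=retrocopy_copies,
            depth=depth,
            error_rate=error_rate,
            mappability=mappability,
        )
        miscalls = 0
        qualities = np.empty(n_reps)
        for i in range(n_reps):
            ref, alt = simulate_pileup(scenario, rng)
            call, qual = genotype_call(ref, alt, error_rate)
            qualities[i] = qual
            if call != true_genotype:
                miscalls += 1
        rows.append(
            {
                "depth": depth,
                "miscall_rate": miscalls / n_reps,
                "mean_quality": float(qualities.mean()),
            }
        )
    return pd.DataFrame(rows)
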