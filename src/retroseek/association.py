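"""Expression association tests for retroduplication parent genes.

Two questions, each answered per population to avoid stratification
confounding: (1) does carrying a retroduplication of a gene shift that
gene's expression (rank-sum per gene, BH adjustment, Fisher omnibus, and a
paired signed-rank cross-check on group medians); (2) do parent genes sit
high in the genome-wide expression distribution (empirical rank test with
Fisher omnibus)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXACT_MAX_N = 10  # exact rank-test null enumerated up to this group size


@dataclass(frozen=True)
class GeneTestResult:
    gene_id: str
    statistic: float
    p_value: float
    p_adjusted: float


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    method = "exact" if max(len(x), len(y)) <= EXACT_MAX_N else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties; fall back to tie-corrected normal
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def eqtl_test(
    expression: pd.DataFrame,
    carrier_status: Mapping[str, Sequence[str]],
    population_individuals: Sequence[str],
) -> list[GeneTestResult]:
    """Per-gene carrier vs non-carrier two-sided rank-sum test.

    ``expression``: genes x individuals. ``carrier_status`` maps gene_id to
    the individuals carrying its retroduplication. Only genes with at least
    one carrier and one non-carrier inside the population are testable;
    zero-variance genes are skipped with a log entry.
    """
    individuals = [i for i in population_individuals if i in expression.columns]
    results: list[tuple[str, float, float]] = []
    for gene_id in sorted(carrier_status):
        if gene_id not in expression.index:
            continue
        carriers = [i for i in individuals if i in set(carrier_status[gene_id])]
        noncarriers = [i for i in individuals if i not in set(carrier_status[gene_id])]
        if not carriers or not noncarriers:
            continue
        expr = expression.loc[gene_id]
        x = expr[carriers].to_numpy(dtype=float)
        y = expr[noncarriers].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            logger.info("gene %s has zero expression variance; skipped", gene_id)
            continue
        stat, p = _rank_sum_test(x, y)
        results.append((gene_id, stat, p))
    if not results:
        return []
    pvals = [p for _, _, p in results]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        GeneTestResult(gene_id=g, statistic=s, p_value=p, p_adjusted=float(a))
        for (g, s, p), a in zip(results, p_adj)
    ]


def omnibus_fisher(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: X2 = -2 sum(ln p) vs chi2(2k)."""
    p_arr = np.asarray(p_values, dtype=float)
    if p_arr.size == 0:
        raise ValueError("need at least one p-value")
    stat, p = stats.combine_pvalues(np.clip(p_arr, 1e-300, 1.0), method="fisher")
    return float(min(p, 1.0))


def paired_signed_rank(
    median_expr_carriers: Sequence[float], median_expr_noncarriers: Sequence[float]
) -> float:
    """Two-sided Wilcoxon signed-rank test pairing per-gene group medians."""
    x = np.asarray(median_expr_carriers, dtype=float)
    y = np.asarray(median_expr_noncarriers, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    diffs = x - y
    if np.all(diffs == 0):
        return 1.0
    method = "exact" if len(diffs) <= 25 else "approx"
    res = stats.wilcoxon(x, y, alternative="two-sided", method=method, zero_method="wilcox")
    return float(min(res.pvalue, 1.0))


def expression_rank_test(
    parent_genes: Sequence[str], expression: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Are parent genes highly expressed among all genes?

    Each gene is represented by its median expression over individuals.
    Per parent gene, the one-tailed empirical p is the fraction of all G
    genes with median >= the parent's (with the +1/(G+1) floor); the
    per-gene p-values are combined with Fisher's method.
    """
    medians = expression.median(axis=1)
    g_total = len(medians)
    rows = []
    for gene in parent_genes:
        if gene not in medians.index:
            continue
        value = medians.loc[gene]
        n_ge = int((medians >= value).sum())
        p = n_ge / (g_total + 1.0)
        rows.append({"gene_id": gene, "median_expression": float(value),
                     "quantile": 1.0 - n_ge / g_total, "p_empirical": p})
    table = pd.DataFrame(rows, columns=["gene_id", "median_expression", "quantile", "p_empirical"])
    if table.empty:
        raise ValueError("no parent genes found in the expression table")
    combined = omnibus_fisher(table["p_empirical"].tolist())
    return table, combined
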