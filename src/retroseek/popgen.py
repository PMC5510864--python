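"""Population-genetic statistics over the retroduplication callset.

The carrier-frequency matrix A (M parent genes x N populations, each entry
the fraction of individuals in the population carrying a retroduplication
of the gene) feeds three analyses:

* a fixation-index statistic per gene over the five superpopulations,
  F_ST = [p(1-p) - sum_i c_i p_i (1-p_i)] / [p(1-p)], with an empirical
  permutation test (label shuffles preserving population sizes) and
  Benjamini-Hochberg adjustment;
* average-linkage hierarchical clustering of populations under Manhattan
  distance, with ordinary bootstrap (BP) and multiscale-bootstrap
  approximately-unbiased (AU) support for each cluster;
* the fraction of parent genes private to a single superpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests


@dataclass
class FrequencyMatrix:
    freq: pd.DataFrame  # genes x populations, values in [0, 1]
    counts: pd.DataFrame  # genes x populations, carrier counts
    pop_sizes: pd.Series  # per population

    def __post_init__(self) -> None:
        if ((self.freq < 0) | (self.freq > 1)).any().any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.freq.index)

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)


@dataclass(frozen=True)
class FstResult:
    gene_id: str
    fst: float
    p_empirical: float
    p_adjusted: float


@dataclass
class Dendrogram:
    """Binary tree over population leaves from scipy average linkage."""

    linkage_matrix: np.ndarray
    labels: list[str]
    bp: dict[frozenset, float] = field(default_factory=dict)
    au: dict[frozenset, float] = field(default_factory=dict)

    def clades(self) -> list[frozenset]:
        """Leaf sets of internal nodes (excluding trivial singletons and root)."""
        n = len(self.labels)
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for k, row in enumerate(self.linkage_matrix):
            a, b = int(row[0]), int(row[1])
            members[n + k] = members[a] | members[b]
            if 1 < len(members[n + k]) < n:
                out.append(members[n + k])
        return out

    def to_newick(self, support: Mapping[frozenset, float] | None = None, digits: int = 2) -> str:
        node = to_tree(self.linkage_matrix)
        n = len(self.labels)

        def leafset(nd) -> frozenset:
            return frozenset(self.labels[i] for i in nd.pre_order(lambda x: x.id))

        def rec(nd, parent_height: float) -> str:
            bl = max(parent_height - nd.dist, 0.0)
            if nd.is_leaf():
                return f"{self.labels[nd.id]}:{bl:.6g}"
            inner = f"{rec(nd.left, nd.dist)},{rec(nd.right, nd.dist)}"
            label = ""
            if support is not None:
                val = support.get(leafset(nd))
                if val is not None:
                    label = f"{val:.{digits}f}"
            return f"({inner}){label}:{bl:.6g}"

        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"


# --- frequency matrix -------------------------------------------------------


def build_frequency_matrix(
    parent_gene_calls: Iterable,
    manifest: pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> FrequencyMatrix:
    """Tabulate distinct carriers per (gene, population) into frequencies.

    ``manifest`` needs columns ``sample`` and ``population``; calls are
    ParentGeneCall-like objects with sample_id and gene_id. ``genes``
    optionally fixes the gene universe (rows without calls are all-zero).
    """
    pops = sorted(manifest["population"].unique())
    pop_sizes = manifest.groupby("population")["sample"].nunique().reindex(pops)
    pop_of = dict(zip(manifest["sample"], manifest["population"]))
    carriers: dict[str, dict[str, set[str]]] = {}
    for call in parent_gene_calls:
        pop = pop_of.get(call.sample_id)
        if pop is None:
            continue
        carriers.setdefault(call.gene_id, {}).setdefault(pop, set()).add(call.sample_id)
    gene_index = sorted(set(carriers) | set(genes or []))
    counts = pd.DataFrame(0, index=gene_index, columns=pops, dtype=int)
    for gene, by_pop in carriers.items():
        for pop, samples in by_pop.items():
            counts.loc[gene, pop] = len(samples)
    freq = counts / pop_sizes if gene_index else counts.astype(float)
    return FrequencyMatrix(freq=freq, counts=counts, pop_sizes=pop_sizes)


# --- fixation index ---------------------------------------------------------


def fst(p_by_group: Sequence[float], c_by_group: Sequence[float]) -> float:
    """F_ST = [p(1-p) - sum_i c_i p_i(1-p_i)] / [p(1-p)] with p = sum c_i p_i.

    Returns 0 when p(1-p) = 0: no variation means no differentiation.
    """
    p_arr = np.asarray(p_by_group, dtype=float)
    c_arr = np.asarray(c_by_group, dtype=float)
    if not np.isclose(c_arr.sum(), 1.0):
        raise ValueError("group weights must sum to 1")
    p = float(np.dot(c_arr, p_arr))
    denom = p * (1.0 - p)
    if denom <= 0:
        return 0.0
    within = float(np.dot(c_arr, p_arr * (1.0 - p_arr)))
    return (denom - within) / denom


def _fst_all_genes(carriers: np.ndarray, group_index: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorized F_ST for every gene. carriers: individuals x genes (0/1)."""
    n_ind = carriers.shape[0]
    sizes = np.bincount(group_index, minlength=n_groups).astype(float)
    c = sizes / n_ind
    p_groups = np.zeros((n_groups, carriers.shape[1]))
    for g in range(n_groups):
        mask = group_index == g
        if sizes[g] > 0:
            p_groups[g] = carriers[mask].mean(axis=0)
    p = c @ p_groups
    denom = p * (1.0 - p)
    within = c @ (p_groups * (1.0 - p_groups))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (denom - within) / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def fst_permutation_test(
    carrier_table: pd.DataFrame,
    superpop_labels: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[FstResult]:
    """One-tailed permutation test of superpopulation differentiation.

    ``carrier_table``: individuals x genes (bool/0-1), ``superpop_labels``
    indexed like its rows. Individual labels are shuffled across the whole
    cohort (group sizes preserved) ``n_perm`` times; empirical
    p = (#{perm F_ST >= observed} + 1) / (n_perm + 1), BH-adjusted across
    genes.
    """
    labels = superpop_labels.loc[carrier_table.index]
    cats = sorted(labels.unique())
    group_index = np.asarray([cats.index(v) for v in labels])
    carriers = carrier_table.to_numpy(dtype=float)
    observed = _fst_all_genes(carriers, group_index, len(cats))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(carriers.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(group_index)
        exceed += _fst_all_genes(carriers, perm, len(cats)) >= observed
    p_emp = (exceed + 1.0) / (n_perm + 1.0)
    _, p_adj, _, _ = multipletests(p_emp, method="fdr_bh")
    return [
        FstResult(gene_id=g, fst=float(observed[i]), p_empirical=float(p_emp[i]), p_adjusted=float(p_adj[i]))
        for i, g in enumerate(carrier_table.columns)
    ]


# --- population trees -------------------------------------------------------


def manhattan_distances(matrix: FrequencyMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Manhattan distance between population frequency columns."""
    freq = matrix.freq if isinstance(matrix, FrequencyMatrix) else matrix
    d = squareform(pdist(freq.to_numpy().T, metric="cityblock"))
    return pd.DataFrame(d, index=freq.columns, columns=freq.columns)


def average_linkage_tree(distances: pd.DataFrame) -> Dendrogram:
    Z = linkage(squareform(distances.to_numpy(), checks=False), method="average")
    return Dendrogram(linkage_matrix=Z, labels=list(distances.index))


def _tree_clades(freq: pd.DataFrame) -> set[frozenset]:
    return set(average_linkage_tree(manhattan_distances(freq)).clades())


def bootstrap_support(
    matrix: FrequencyMatrix | pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> tuple[Dendrogram, dict[frozenset, float]]:
    """Ordinary bootstrap support: resample gene rows with replacement and
    count how often each full-data cluster recurs in replicate trees."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    freq = matrix.freq if isinstance(matrix, FrequencyMatrix) else matrix
    tree = average_linkage_tree(manhattan_distances(freq))
    target = tree.clades()
    hits = {cl: 0 for cl in target}
    rng = np.random.default_rng(seed)
    m = freq.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        rep = _tree_clades(freq.iloc[idx])
        for cl in target:
            if cl in rep:
                hits[cl] += 1
    bp = {cl: hits[cl] / n_boot for cl in target}
    tree.bp = bp
    return tree, bp


DEFAULT_AU_SCALES = tuple(np.round(np.linspace(0.5, 1.4, 10), 2))


def au_support(
    matrix: FrequencyMatrix | pd.DataFrame,
    scales: Sequence[float] = DEFAULT_AU_SCALES,
    n_boot_per_scale: int = 1000,
    seed: int = 0,
) -> tuple[Dendrogram, dict[frozenset, float]]:
    """Approximately-unbiased cluster support from multiscale bootstrap.

    For each scale ratio rho, ceil(rho*M) gene rows are resampled and the
    per-cluster bootstrap probability BP(rho) recorded. The signed distance
    and curvature (v, c) are fit to z(rho) = Phi^-1(1 - BP) ~ v*sqrt(rho)
    + c/sqrt(rho) by weighted least squares (weights n*phi(z)^2/(BP(1-BP)));
    AU = 1 - Phi(v - c). Clusters with degenerate BP (0 or 1) at more than
    half the scales fall back to BP at the scale closest to 1.
    """
    if n_boot_per_scale < 1:
        raise ValueError("n_boot_per_scale must be >= 1")
    freq = matrix.freq if isinstance(matrix, FrequencyMatrix) else matrix
    tree = average_linkage_tree(manhattan_distances(freq))
    target = tree.clades()
    m = freq.shape[0]
    rng = np.random.default_rng(seed)
    bp_by_scale: dict[float, dict[frozenset, float]] = {}
    for rho in scales:
        m_rho = max(1, int(np.ceil(rho * m)))
        hits = {cl: 0 for cl in target}
        for _ in range(n_boot_per_scale):
            idx = rng.integers(0, m, size=m_rho)
            rep = _tree_clades(freq.iloc[idx])
            for cl in target:
                if cl in rep:
                    hits[cl] += 1
        bp_by_scale[rho] = {cl: hits[cl] / n_boot_per_scale for cl in target}
    ref_scale = min(scales, key=lambda s: abs(s - 1.0))
    au: dict[frozenset, float] = {}
    for cl in target:
        rhos, bps = [], []
        for rho in scales:
            bp = bp_by_scale[rho][cl]
            if 0.0 < bp < 1.0:
                rhos.append(rho)
                bps.append(bp)
        if len(rhos) < len(scales) / 2 or len(rhos) < 2:
            au[cl] = bp_by_scale[ref_scale][cl]  # degenerate profile: fall back to BP
            continue
        _, _, au_val = fit_au(rhos, bps, n_boot_per_scale)
        au[cl] = au_val
    tree.au = au
    return tree, au


def fit_au(
    scales: Sequence[float], bp_values: Sequence[float], n_boot: int
) -> tuple[float, float, float]:
    """Weighted least-squares fit of the multiscale bootstrap profile.

    z(rho) = Phi^-1(1 - BP(rho)) is modelled as v*sqrt(rho) + c/sqrt(rho)
    (signed distance v, curvature c); weights are n*phi(z)^2/(BP(1-BP)).
    Returns (v, c, AU) with AU = 1 - Phi(v - c).
    """
    rhos_a = np.asarray(scales, dtype=float)
    bps_a = np.asarray(bp_values, dtype=float)
    if np.any((bps_a <= 0) | (bps_a >= 1)):
        raise ValueError("BP values must lie strictly in (0, 1)")
    z = norm.ppf(1.0 - bps_a)
    X = np.column_stack([np.sqrt(rhos_a), 1.0 / np.sqrt(rhos_a)])
    w = n_boot * norm.pdf(z) ** 2 / (bps_a * (1.0 - bps_a))
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
    v, c = (float(coef[0]), float(coef[1]))
    return v, c, float(np.clip(1.0 - norm.cdf(v - c), 0.0, 1.0))


def private_superpop_fraction(
    matrix: FrequencyMatrix | pd.DataFrame, superpop_map: Mapping[str, str]
) -> float:
    """Fraction of called genes whose carriers all lie in one superpopulation."""
    freq = matrix.freq if isinstance(matrix, FrequencyMatrix) else matrix
    superpops = pd.Series({pop: superpop_map[pop] for pop in freq.columns})
    nonzero = freq > 0
    called = nonzero.any(axis=1)
    if not called.any():
        return 0.0
    n_private = 0
    for gene in freq.index[called]:
        present = superpops[nonzero.loc[gene]].unique()
        if len(present) == 1:
            n_private += 1
    return n_private / int(called.sum())
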