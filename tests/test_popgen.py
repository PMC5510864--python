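import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from retroseek import (
    FrequencyMatrix,
    au_support,
    average_linkage_tree,
    bootstrap_support,
    build_frequency_matrix,
    fst,
    fst_permutation_test,
    manhattan_distances,
    private_superpop_fraction,
)
from retroseek.junction_caller import ParentGeneCall
from retroseek.popgen import fit_au
from retroseek import synthetic_data as sd


def _manifest(sizes):
    rows = []
    for pop, n in sizes.items():
        for i in range(n):
            rows.append({"sample": f"{pop}_{i}", "population": pop})
    return pd.DataFrame(rows)


def _call(sample, gene):
    return ParentGeneCall(sample_id=sample, gene_id=gene, supporting_junctions=[])


class TestFrequencyMatrix:
    def test_carrier_fraction_arithmetic(self):
        manifest = _manifest({"A": 10, "B": 8})
        calls = [_call(f"A_{i}", "G1") for i in range(3)]
        fm = build_frequency_matrix(calls, manifest)
        assert fm.freq.loc["G1", "A"] == pytest.approx(0.3)
        assert fm.freq.loc["G1", "B"] == 0.0

    def test_empty_calls_all_zero(self):
        fm = build_frequency_matrix([], _manifest({"A": 5}), genes=["G1", "G2"])
        assert (fm.freq.to_numpy() == 0).all()
        assert fm.freq.shape == (2, 1)

    def test_duplicate_calls_counted_once(self):
        manifest = _manifest({"A": 4})
        calls = [_call("A_0", "G1"), _call("A_0", "G1")]
        fm = build_frequency_matrix(calls, manifest)
        assert fm.counts.loc["G1", "A"] == 1

    def test_invalid_frequency_rejected(self):
        freq = pd.DataFrame({"A": [1.5]}, index=["G1"])
        with pytest.raises(ValueError):
            FrequencyMatrix(freq=freq, counts=freq, pop_sizes=pd.Series({"A": 2}))


class TestFst:
    def test_equal_frequencies_give_zero(self):
        assert fst([0.3, 0.3, 0.3], [0.2, 0.5, 0.3]) == pytest.approx(0.0, abs=1e-12)

    def test_full_differentiation_gives_one(self):
        assert fst([0.0, 1.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_hand_example(self):
        assert fst([0.2, 0.8], [0.5, 0.5]) == pytest.approx(0.36)

    def test_degenerate_monomorphic_returns_zero(self):
        assert fst([1.0, 1.0], [0.5, 0.5]) == 0.0
        assert fst([0.0, 0.0], [0.5, 0.5]) == 0.0

    def test_bounded_on_random_inputs(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            p = rng.random(k)
            c = rng.dirichlet(np.ones(k))
            value = fst(p, c)
            assert 0.0 <= value <= 1.0 + 1e-12

    def test_weights_must_normalize(self):
        with pytest.raises(ValueError):
            fst([0.1, 0.2], [0.7, 0.2])


class TestFstPermutation:
    def _null_cohort(self, n_ind=150, n_genes=200, seed=3):
        rng = np.random.default_rng(seed)
        carriers = pd.DataFrame(
            rng.random((n_ind, n_genes)) < 0.2,
            index=[f"i{k}" for k in range(n_ind)],
            columns=[f"G{k}" for k in range(n_genes)],
        )
        labels = pd.Series(
            rng.choice(["AFR", "AMR", "EAS", "EUR", "SAS"], size=n_ind),
            index=carriers.index,
        )
        return carriers, labels

    def test_null_pvalues_uniform_within_dkw_band(self):
        """Labels carry no signal: empirical p-values are uniform; the ECDF
        stays inside the 99% Dvoretzky-Kiefer-Wolfowitz band."""
        carriers, labels = self._null_cohort()
        results = fst_permutation_test(carriers, labels, n_perm=300, seed=7)
        p = np.sort([r.p_empirical for r in results])
        n = len(p)
        eps = np.sqrt(np.log(2 / 0.01) / (2 * n))
        ecdf = np.arange(1, n + 1) / n
        assert np.max(np.abs(ecdf - p)) < eps + 1.0 / 301  # permutation granularity

    def test_type_i_rate_within_binomial_bounds(self):
        carriers, labels = self._null_cohort(seed=11)
        results = fst_permutation_test(carriers, labels, n_perm=300, seed=5)
        rate = np.mean([r.p_empirical <= 0.05 for r in results])
        # 200 genes at alpha=0.05: 3-sigma binomial envelope
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_constant_gene_has_zero_fst_and_p_near_one(self):
        carriers, labels = self._null_cohort()
        carriers["Gconst"] = True
        results = fst_permutation_test(carriers, labels, n_perm=100, seed=2)
        const = [r for r in results if r.gene_id == "Gconst"][0]
        assert const.fst == 0.0
        assert const.p_empirical > 0.9

    def test_planted_superpop_specific_genes_detected(self):
        """Genes at frequency 0.8 in one superpopulation and 0 elsewhere
        reach BH-adjusted empirical p < 0.001 (several such genes must be
        present for the BH rank to allow it at permutation granularity)."""
        rng = np.random.default_rng(21)
        sizes = {"AFR": 100, "AMR": 100, "EAS": 100, "EUR": 100, "SAS": 100}
        index = [f"{sp}_{i}" for sp, n in sizes.items() for i in range(n)]
        labels = pd.Series([i.split("_")[0] for i in index], index=index)
        carriers = pd.DataFrame(
            rng.random((len(index), 12)) < 0.1, index=index,
            columns=[f"G{k}" for k in range(12)],
        )
        planted = []
        for j, sp in enumerate(("AFR", "AMR", "EAS", "EUR", "SAS", "AFR", "EAS", "EUR")):
            name = f"Gprivate{j}"
            carriers[name] = [labels[i] == sp and rng.random() < 0.8 for i in index]
            planted.append(name)
        results = fst_permutation_test(carriers, labels, n_perm=5000, seed=4)
        for name in planted:
            hit = [r for r in results if r.gene_id == name][0]
            assert hit.p_adjusted < 0.001

    def test_reproducible_under_seed(self):
        carriers, labels = self._null_cohort(n_ind=40, n_genes=10)
        a = fst_permutation_test(carriers, labels, n_perm=50, seed=9)
        b = fst_permutation_test(carriers, labels, n_perm=50, seed=9)
        assert a == b


class TestTrees:
    def _matrix(self):
        # three populations: A and B identical, C distant
        freq = pd.DataFrame(
            {"A": [0.9, 0.1, 0.5], "B": [0.9, 0.1, 0.5], "C": [0.0, 0.9, 0.0]},
            index=["G1", "G2", "G3"],
        )
        return freq

    def test_distance_matrix_properties(self):
        d = manhattan_distances(self._matrix())
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d.loc["A", "B"] == 0.0
        assert d.loc["A", "C"] == pytest.approx(0.9 + 0.8 + 0.5)

    def test_identical_columns_merge_first(self):
        tree = average_linkage_tree(manhattan_distances(self._matrix()))
        assert frozenset({"A", "B"}) in tree.clades()

    def test_three_population_tree_matches_brute_force(self):
        """Exhaustive agglomeration over a 4-leaf example."""
        freq = pd.DataFrame(
            {"A": [1.0, 0.0], "B": [0.9, 0.1], "C": [0.0, 1.0], "D": [0.1, 0.8]},
            index=["G1", "G2"],
        )
        d = manhattan_distances(freq)
        # brute force: greedy average-linkage merges
        clusters = [frozenset([p]) for p in freq.columns]
        dist = {(a, b): d.loc[list(a)[0], list(b)[0]] for a, b in itertools.combinations(clusters, 2)}

        def avg(c1, c2):
            return np.mean([d.loc[x, y] for x in c1 for y in c2])

        merges = []
        while len(clusters) > 1:
            best = min(itertools.combinations(clusters, 2), key=lambda ab: avg(*ab))
            clusters.remove(best[0]); clusters.remove(best[1])
            merged = best[0] | best[1]
            clusters.append(merged)
            merges.append(merged)
        tree = average_linkage_tree(d)
        assert set(tree.clades()) == {m for m in merges if 1 < len(m) < 4}

    def test_tree_invariant_to_gene_row_order(self):
        freq = self._matrix()
        t1 = average_linkage_tree(manhattan_distances(freq))
        t2 = average_linkage_tree(manhattan_distances(freq.iloc[::-1]))
        assert set(t1.clades()) == set(t2.clades())

    def test_newick_output_contains_all_leaves(self):
        tree = average_linkage_tree(manhattan_distances(self._matrix()))
        nwk = tree.to_newick()
        for leaf in "ABC":
            assert leaf in nwk
        assert nwk.endswith(";")


def _structured_freq(n_genes_per_sp=40, high=0.6, low=0.02, seed=0):
    """Frequency matrix with one block of informative genes per superpopulation."""
    rng = np.random.default_rng(seed)
    pops = sd.all_populations()
    spmap = sd.superpop_map()
    superpops = sorted(set(spmap.values()))
    rows = {}
    g = 0
    for sp in superpops:
        for _ in range(n_genes_per_sp):
            base = rng.uniform(0, low, size=len(pops))
            for k, pop in enumerate(pops):
                if spmap[pop] == sp:
                    base[k] = high + rng.uniform(-0.1, 0.1)
            rows[f"G{g:03d}"] = base
            g += 1
    return pd.DataFrame.from_dict(rows, orient="index", columns=pops)


class TestBootstrap:
    def test_planted_superpopulation_blocks_recovered_with_high_bp(self):
        freq = _structured_freq(n_genes_per_sp=40, seed=1)
        tree, bp = bootstrap_support(freq, n_boot=200, seed=2)
        spmap = sd.superpop_map()
        for sp in ("AFR", "EAS", "EUR", "SAS", "AMR"):
            clade = frozenset(p for p in freq.columns if spmap[p] == sp)
            assert clade in bp, f"{sp} not monophyletic in the point tree"
            assert bp[clade] >= 0.95

    def test_bp_in_unit_interval_and_seeded(self):
        freq = _structured_freq(n_genes_per_sp=5, seed=3)
        _, bp1 = bootstrap_support(freq, n_boot=50, seed=4)
        _, bp2 = bootstrap_support(freq, n_boot=50, seed=4)
        assert bp1 == bp2
        assert all(0.0 <= v <= 1.0 for v in bp1.values())

    def test_zero_bootstraps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(_structured_freq(5), n_boot=0)


class TestAuSupport:
    def test_curvature_free_profile_gives_au_equal_bp_at_unit_scale(self):
        # c = 0: z = v*sqrt(rho); AU = 1 - Phi(v) = BP at rho = 1 exactly
        v = 0.7
        rhos = np.linspace(0.5, 1.4, 10)
        bps = 1.0 - norm.cdf(v * np.sqrt(rhos))
        v_hat, c_hat, au = fit_au(rhos, bps, n_boot=1000)
        assert c_hat == pytest.approx(0.0, abs=1e-8)
        bp_at_1 = 1.0 - norm.cdf(v)
        assert au == pytest.approx(bp_at_1, abs=1e-8)

    def test_known_parameters_recovered(self):
        v, c = 1.1, 0.35
        rhos = np.linspace(0.5, 1.4, 10)
        bps = 1.0 - norm.cdf(v * np.sqrt(rhos) + c / np.sqrt(rhos))
        v_hat, c_hat, au = fit_au(rhos, bps, n_boot=1000)
        assert v_hat == pytest.approx(v, abs=1e-6)
        assert c_hat == pytest.approx(c, abs=1e-6)
        assert au == pytest.approx(1.0 - norm.cdf(v - c), abs=1e-6)

    def test_au_values_in_unit_interval_on_data(self):
        freq = _structured_freq(n_genes_per_sp=8, seed=5)
        _, au = au_support(freq, n_boot_per_scale=40, seed=6)
        assert all(0.0 <= v <= 1.0 for v in au.values())

    def test_degenerate_profile_rejected_by_fit(self):
        with pytest.raises(ValueError):
            fit_au([0.5, 1.0], [0.0, 0.5], n_boot=100)


class TestPrivateFraction:
    def test_extremes(self):
        pops = sd.all_populations()
        spmap = sd.superpop_map()
        global_freq = pd.DataFrame(0.5, index=["G1", "G2"], columns=pops)
        assert private_superpop_fraction(global_freq, spmap) == 0.0
        private = pd.DataFrame(0.0, index=["G1"], columns=pops)
        private.loc["G1", [p for p in pops if spmap[p] == "EAS"]] = 0.4
        assert private_superpop_fraction(private, spmap) == 1.0

    def test_hand_tabulated_fixture(self):
        pops = sd.all_populations()
        spmap = sd.superpop_map()
        freq = pd.DataFrame(0.0, index=[f"G{i}" for i in range(10)], columns=pops)
        afr = [p for p in pops if spmap[p] == "AFR"]
        for i in range(7):  # 7 of 10 genes AFR-private
            freq.loc[f"G{i}", afr] = 0.3
        freq.loc["G7"] = 0.2
        freq.loc["G8"] = 0.1
        freq.loc["G9", [afr[0], "CEU"]] = 0.2
        assert private_superpop_fraction(freq, spmap) == pytest.approx(0.7)
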