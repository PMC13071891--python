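"""Statistics: GC, Wilcoxon, chi-square, TPM, enrichment, BH, translation."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from nanohgt.featstats import (
    EUPLOTID_TABLE,
    STANDARD_TABLE,
    bh_adjust,
    chi_square_independence,
    gc_content,
    hypergeometric_enrichment,
    mic_dispersion,
    tpm,
    translate_orf,
    wilcoxon_rank_sum,
)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("GATC", 0.5), ("GCNNAT", 0.5)]
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")


def _brute_force_p(x, y):
    """Independent oracle: full enumeration of rank assignments."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    w_obs = sum(ranks[: len(x)])
    ws = [sum(ranks[i] for i in idx)
          for idx in combinations(range(len(pooled)), len(x))]
    n_le = sum(w <= w_obs + 1e-9 for w in ws)
    n_ge = sum(w >= w_obs - 1e-9 for w in ws)
    return min(1.0, 2.0 * min(n_le, n_ge) / len(ws))


class TestWilcoxon:
    def test_exact_small_example(self):
        # x ranks sum to 3; only {1,2} of C(4,2)=6 subsets is as extreme
        res = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "wilcoxon_exact"

    def test_identical_samples_center_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="exact")
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 8, size=2)
        x = list(np.round(rng.normal(size=n), 3))
        y = list(np.round(rng.normal(0.5, size=m), 3))
        res = wilcoxon_rank_sum(x, y, mode="exact")
        assert res.p_value == pytest.approx(_brute_force_p(x, y))

    def test_exact_handles_ties_via_midranks(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        res = wilcoxon_rank_sum(x, y, mode="exact")
        assert res.p_value == pytest.approx(_brute_force_p(x, y))

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        x = list(rng.normal(size=6))
        y = list(rng.normal(size=7))
        mine = wilcoxon_rank_sum(x, y, mode="exact").p_value
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert mine == pytest.approx(float(ref))

    def test_normal_close_to_exact_at_n8(self):
        rng = np.random.default_rng(11)
        x = list(rng.normal(size=8))
        y = list(rng.normal(size=8))
        p_exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
        p_norm = wilcoxon_rank_sum(x, y, mode="normal").p_value
        assert abs(p_exact - p_norm) < 0.02

    def test_auto_mode_switches_on_size_and_ties(self):
        small = wilcoxon_rank_sum([1, 2], [3, 4], mode="auto")
        assert small.method == "wilcoxon_exact"
        tied = wilcoxon_rank_sum([1, 1, 2], [2, 3, 4], mode="auto")
        assert tied.method == "wilcoxon_normal"
        big = wilcoxon_rank_sum(list(range(20)), list(range(100, 120)), mode="auto")
        assert big.method == "wilcoxon_normal"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        res = chi_square_independence([[10, 90], [10, 90]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pearson_statistic(self):
        # margins: rows 100/100, cols 30/170; E = [[15,85],[15,85]]
        # chi2 = sum (O-E)^2/E = 25/15*2 + 25/85*2 = 3.92156...
        res = chi_square_independence([[20, 80], [10, 90]])
        expected = 2 * (25 / 15) + 2 * (25 / 85)
        assert res.statistic == pytest.approx(expected)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, df=1))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 5]])


class TestTpm:
    @pytest.mark.parametrize(
        "counts,lengths,expected",
        [
            ((10, 10), (100, 100), (5e5, 5e5)),
            ((10, 20), (100, 200), (5e5, 5e5)),  # equal per-bp rates
            ((0, 10), (100, 100), (0.0, 1e6)),
        ],
    )
    def test_values(self, counts, lengths, expected):
        assert tpm(counts, lengths) == pytest.approx(expected)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            tpm([0, 0], [100, 100])

    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=30),
        st.data(),
    )
    def test_conservation_sums_to_one_million(self, counts, data):
        if sum(counts) == 0:
            counts[0] = 1
        lengths = data.draw(
            st.lists(
                st.integers(min_value=50, max_value=5000),
                min_size=len(counts),
                max_size=len(counts),
            )
        )
        assert tpm(counts, lengths).sum() == pytest.approx(1e6, rel=1e-6)


def _hypergeom_enumeration_p(N, K, n, k):
    """Oracle: exhaustive count of n-draws with >= k marked elements."""
    hits = sum(
        comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    )
    return hits / comb(N, n)


class TestEnrichment:
    def test_perfect_overlap_exact_p(self):
        universe = [f"g{i}" for i in range(10)]
        study = universe[:5]
        ann = {g: ["T"] for g in study}
        rows = hypergeometric_enrichment(study, ann, universe)
        assert rows[0].p == pytest.approx(1 / 252)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        ann = {"g9": ["T"]}
        rows = hypergeometric_enrichment(universe[:3], ann, universe)
        assert rows[0].k == 0 and rows[0].p == pytest.approx(1.0)

    def test_single_term_q_equals_p(self):
        universe = [f"g{i}" for i in range(8)]
        ann = {"g0": ["T"], "g1": ["T"]}
        rows = hypergeometric_enrichment(universe[:4], ann, universe)
        assert len(rows) == 1 and rows[0].q == pytest.approx(rows[0].p)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_draw_enumeration_small_universe(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 13))
        universe = [f"g{i}" for i in range(N)]
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        ann = {g: ["T"] for g in universe[:K]}
        study = list(rng.choice(universe, size=n, replace=False))
        rows = hypergeometric_enrichment(study, ann, universe)
        k = len(set(study) & set(universe[:K]))
        assert rows[0].p == pytest.approx(_hypergeom_enumeration_p(N, K, n, k))

    def test_study_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeometric_enrichment(["x"], {}, ["g0"])


class TestBhAdjust:
    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_singleton_unchanged(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(ref)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_order_equivariant_and_dominates_p(self, p, rnd):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12) and np.all(q <= 1.0)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q_perm = bh_adjust([p[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestTranslateOrf:
    def _stop_free_orf(self, n_nt, seed=0):
        rng = np.random.default_rng(seed)
        codons = []
        while len(codons) < n_nt // 3:
            c = "".join(rng.choice(list("ACGT"), size=3))
            if c not in {"TAA", "TAG"}:  # Euplotid stops only
                codons.append(c)
        return "".join(codons)

    def test_1209_nt_orf_gives_403_residues(self):
        protein = translate_orf(self._stop_free_orf(1209))
        assert len(protein) == 403

    def test_1260_nt_orf_gives_420_residues(self):
        protein = translate_orf(self._stop_free_orf(1260, seed=1))
        assert len(protein) == 420

    def test_uga_is_cysteine_under_euplotid_code(self):
        assert translate_orf("ATGTGA", EUPLOTID_TABLE) == "MC"
        with pytest.raises(ValueError, match="position 2"):
            translate_orf("ATGTGA", STANDARD_TABLE)

    def test_internal_stop_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            translate_orf("ATGTAAATG", EUPLOTID_TABLE)

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            translate_orf("ATGC")

    @given(st.integers(min_value=1, max_value=200), st.integers(0, 2**31 - 1))
    def test_length_contract(self, n_codons, seed):
        dna = self._stop_free_orf(3 * n_codons, seed=seed)
        assert len(translate_orf(dna)) == n_codons


class TestMicDispersion:
    def test_one_gene_per_scaffold(self):
        m = {f"g{i}": f"s{i}" for i in range(5)}
        assert mic_dispersion(m) == (5, 5, 1)

    def test_two_genes_per_scaffold(self):
        m = {"g1": "s1", "g2": "s1", "g3": "s2", "g4": "s2"}
        assert mic_dispersion(m) == (4, 2, 2)

    def test_simulated_map_matches_truth(self, sim_dataset, sim_truth):
        n_genes, n_scaf, max_per = mic_dispersion(sim_truth.mic_map)
        assert n_genes == len(sim_truth.genes_of_class("HGT"))
        counts = {}
        for s in sim_truth.mic_map.values():
            counts[s] = counts.get(s, 0) + 1
        assert n_scaf == len(counts) and max_per == max(counts.values())

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            mic_dispersion({})
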