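"""AMOVA, permutation inference, Holm correction and the Mantel test."""

import itertools
import math

import numpy as np
import pytest

from hapstruct.dataio import CountTable, DataError, HaplotypeCatalog
from hapstruct.distances import DistanceMatrix, identity_matrix, tn93_matrix
from hapstruct.structure import (
    amova,
    holm_initial_alpha,
    mantel_test,
    pairwise_structure,
    sequential_bonferroni,
)


def brute_force_amova(pop_sequences, dist_of):
    """Individual-level oracle: explicit double loops over individuals.

    pop_sequences: list of lists of haplotype labels per population;
    dist_of(a, b): distance between two labels.
    """
    all_ind = [h for pop in pop_sequences for h in pop]
    N, J = len(all_ind), len(pop_sequences)
    ss_total = sum(
        dist_of(all_ind[i], all_ind[j]) ** 2
        for i in range(N)
        for j in range(i + 1, N)
    ) / N
    ss_within = 0.0
    for pop in pop_sequences:
        nj = len(pop)
        ss_within += sum(
            dist_of(pop[i], pop[j]) ** 2
            for i in range(nj)
            for j in range(i + 1, nj)
        ) / nj
    ss_among = ss_total - ss_within
    sigma_b = ss_within / (N - J)
    n_prime = (N - sum(len(p) ** 2 for p in pop_sequences) / N) / (J - 1)
    sigma_a = (ss_among / (J - 1) - sigma_b) / n_prime
    return sigma_a / (sigma_a + sigma_b)


class TestAmova:
    def test_published_overall_f_st(self, spinner):
        _, ct = spinner
        res = amova(ct, identity_matrix(ct.haplotypes), n_perm=0)
        assert res.fixation_index == pytest.approx(0.01493, abs=5e-6)
        assert res.ss_among == pytest.approx(2.475, abs=5e-4)
        assert res.ss_within == pytest.approx(142.742, abs=5e-4)
        assert res.var_among == pytest.approx(0.00508, abs=5e-6)
        assert res.var_within == pytest.approx(0.33507, abs=5e-6)
        pa, pw = res.pct_variation
        assert pa == pytest.approx(1.49, abs=0.005)
        assert pa + pw == pytest.approx(100.0)

    def test_fixed_populations_index_one(self):
        ct = CountTable(["A", "B"], ["h1", "h2"], np.array([[5, 0], [0, 5]]))
        res = amova(ct, identity_matrix(["h1", "h2"]), n_perm=2000, seed=0)
        assert res.fixation_index == pytest.approx(1.0)
        # minimum attainable p for complete fixation
        assert res.p <= 0.01

    def test_matches_individual_level_oracle(self, rng):
        # small instances, identity and arbitrary metric
        for trial in range(10):
            K = int(rng.integers(2, 4))
            labels = [f"h{i}" for i in range(K)]
            d = rng.random((K, K))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            dist = DistanceMatrix(labels, d)
            counts = rng.integers(1, 4, size=(K, 3))
            ct = CountTable(["a", "b", "c"], labels, counts)
            res = amova(ct, dist, n_perm=0)
            pops = [
                [labels[i] for i in range(K) for _ in range(counts[i, j])]
                for j in range(3)
            ]
            idx = {l: i for i, l in enumerate(labels)}
            oracle = brute_force_amova(pops, lambda x, y: d[idx[x], idx[y]])
            assert res.fixation_index == pytest.approx(oracle, rel=1e-10)

    def test_index_invariant_to_distance_scaling(self, spinner):
        _, ct = spinner
        base = identity_matrix(ct.haplotypes)
        scaled = DistanceMatrix(base.ids, base.d * 7.3)
        r1 = amova(ct, base, n_perm=0)
        r2 = amova(ct, scaled, n_perm=0)
        assert r1.fixation_index == pytest.approx(r2.fixation_index, rel=1e-12)

    def test_identity_equals_uniform_tn93_path(self):
        # haplotypes built so all pairwise TN93 distances are equal; the
        # fixation index then matches the identity-metric F_ST exactly
        # disjoint A->G mutation pairs: every pair differs by 4 transitions
        tail = "ACGT" * 10
        cat = HaplotypeCatalog(
            {
                "h1": "GGAAAA" + tail,
                "h2": "AAGGAA" + tail,
                "h3": "AAAAGG" + tail,
            }
        )
        dist = tn93_matrix(cat)
        off = dist.d[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0])
        ct = CountTable(["x", "y"], cat.ids, np.array([[4, 1], [1, 3], [2, 2]]))
        phi = amova(ct, dist, n_perm=0).fixation_index
        fst = amova(ct, identity_matrix(cat.ids), n_perm=0).fixation_index
        assert phi == pytest.approx(fst, rel=1e-10)

    def test_merging_identical_populations_stable(self, spinner):
        _, ct = spinner
        dist = identity_matrix(ct.haplotypes)
        # duplicate NSW as a fifth population with identical frequencies
        counts = np.column_stack([ct.counts, ct.pop_counts("NSW")])
        ct5 = CountTable(ct.populations + ["NSW2"], ct.haplotypes, counts)
        r4 = amova(ct, dist, n_perm=0).fixation_index
        r5 = amova(ct5, dist, n_perm=0).fixation_index
        assert abs(r4 - r5) < 0.01

    def test_degenerate_one_individual_per_pop(self):
        ct = CountTable(["a", "b"], ["h1", "h2"], np.array([[1, 0], [0, 1]]))
        with pytest.raises(DataError):
            amova(ct, identity_matrix(["h1", "h2"]), n_perm=0)

    def test_permutation_p_reproducible(self, spinner):
        _, ct = spinner
        dist = identity_matrix(ct.haplotypes)
        p1 = amova(ct, dist, n_perm=1000, seed=77).p
        p2 = amova(ct, dist, n_perm=1000, seed=77).p
        assert p1 == p2


class TestPairwise:
    def test_published_pairwise_values(self, spinner):
        _, ct = spinner
        pw = pairwise_structure(ct, identity_matrix(ct.haplotypes), n_perm=0)
        assert pw.stat[("NSW", "South Africa")] == pytest.approx(0.04056, abs=5e-6)
        assert pw.stat[("NSW", "QLD")] == pytest.approx(0.01151, abs=5e-6)
        assert pw.stat[("QLD", "NT")] == pytest.approx(-0.00704, abs=5e-6)
        assert pw.stat[("NT", "South Africa")] == pytest.approx(0.01411, abs=5e-6)

    def test_population_against_its_copy_not_positive(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 8, size=6) + np.array([3, 0, 0, 0, 0, 0])
        ct = CountTable(
            ["a", "b"], [f"h{i}" for i in range(6)],
            np.column_stack([counts, counts]),
        )
        res = amova(ct, identity_matrix(ct.haplotypes), n_perm=0)
        assert res.fixation_index <= 0

    def test_holm_flags_attached(self, spinner):
        _, ct = spinner
        pw = pairwise_structure(
            ct, identity_matrix(ct.haplotypes), n_perm=500, seed=3
        )
        assert set(pw.significant_after_holm) == set(pw.stat)


class TestSequentialBonferroni:
    def test_first_threshold_for_six_comparisons(self):
        assert holm_initial_alpha(6, 0.05) == pytest.approx(0.008333, abs=5e-7)

    def test_all_ones_none_significant(self):
        assert not sequential_bonferroni([1.0] * 6).any()

    def test_matches_hand_evaluated_chain(self):
        p = [0.001, 0.009, 0.011, 0.2, 0.3, 0.4]
        # hand evaluation: thresholds 0.05/6, 0.05/5, 0.05/4, ...
        expected = []
        passed = True
        for i, pi in enumerate(sorted(p)):
            passed = passed and pi <= 0.05 / (6 - i)
            expected.append(passed)
        order = np.argsort(p)
        flags = sequential_bonferroni(p)
        assert [flags[j] for j in order] == expected

    def test_brute_force_random_lists(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 8))
            p = rng.random(k)
            flags = sequential_bonferroni(p, alpha=0.05)
            order = np.argsort(p)
            passed = True
            for rank, j in enumerate(order):
                passed = passed and p[j] <= 0.05 / (k - rank)
                assert flags[j] == passed


class TestMantel:
    def _random_sym(self, rng, k):
        a = rng.random((k, k))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return a

    def test_perfect_positive_correlation(self, rng):
        a = self._random_sym(rng, 5)
        gen = DistanceMatrix(list("abcde"), a)
        geo = DistanceMatrix(list("abcde"), 3.0 * a)
        res = mantel_test(gen, geo, n_perm=500, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_perfect_negative_correlation(self, rng):
        a = self._random_sym(rng, 5)
        b = a.max() + 1 - a
        np.fill_diagonal(b, 0)
        gen = DistanceMatrix(list("abcde"), a)
        geo = DistanceMatrix(list("abcde"), b)
        res = mantel_test(gen, geo, n_perm=500, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_exact_enumeration_matches_oracle(self, rng):
        k = 4
        gen = DistanceMatrix(list("wxyz"), self._random_sym(rng, k))
        geo = DistanceMatrix(list("wxyz"), self._random_sym(rng, k))
        res = mantel_test(gen, geo, n_perm=9999)
        assert res.exact
        # independent oracle: enumerate all 4! = 24 joint permutations
        tri = np.tril_indices(k, -1)
        x = gen.d[tri]
        r_obs = np.corrcoef(x, geo.d[tri])[0, 1]
        hits = 0
        for perm in itertools.permutations(range(k)):
            y = geo.d[np.ix_(perm, perm)][tri]
            if np.corrcoef(x, y)[0, 1] >= r_obs:
                hits += 1
        assert res.p == pytest.approx(hits / math.factorial(k))

    def test_agrees_with_skbio_r(self, rng):
        # independent implementation cross-check of the statistic
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as skbio_mantel

        k = 6
        a, b = self._random_sym(rng, k), self._random_sym(rng, k)
        ids = [f"s{i}" for i in range(k)]
        r_ours = mantel_test(
            DistanceMatrix(ids, a), DistanceMatrix(ids, b), n_perm=100, seed=0
        ).r
        r_ref, _, _ = skbio_mantel(
            skbio.DistanceMatrix(a, ids), skbio.DistanceMatrix(b, ids),
            permutations=0,
        )
        assert r_ours == pytest.approx(float(r_ref), rel=1e-10)

    def test_constant_matrix_rejected(self):
        ones = identity_matrix(list("abcd"))
        with pytest.raises(DataError):
            mantel_test(ones, ones, n_perm=10)
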