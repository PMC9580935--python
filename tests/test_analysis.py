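import itertools

import numpy as np
import pytest

from straindecon import (
    StrainClusterSet,
    cocluster,
    dereplicate,
    discretize,
    dominant_strain,
    genomewide_ld90,
    ld_decay_profile,
    ld_windows,
    pairwise_ld,
    permutation_enrichment,
)
from straindecon.analysis import _enrichment_statistic

NA = float("nan")


class TestDiscretize:
    @pytest.mark.parametrize("value,expected", [(0.99, 1), (0.01, 0), (0.5, 1)])
    def test_rounding(self, value, expected):
        assert discretize(np.array([[value]]))[0, 0] == expected

    def test_idempotent_and_preserves_missing(self):
        g = np.array([[0.0, 1.0, NA]])
        out = discretize(discretize(g))
        assert out[0, 0] == 0 and out[0, 1] == 1 and np.isnan(out[0, 2])


class TestDereplicate:
    def test_identical_strains_merge_and_sum_abundance(self):
        g = np.array([[0, 1, 1, 0], [0, 1, 1, 0], [1, 0, 0, 1]], float)
        pi = np.array([[0.3, 0.2, 0.5]])
        g2, p2 = dereplicate(g, pi, threshold=0.05)
        assert g2.shape[0] == 2
        assert sorted(p2[0]) == pytest.approx([0.5, 0.5])
        np.testing.assert_allclose(p2.sum(axis=1), 1.0)

    def test_distant_strains_not_merged(self):
        g = np.array([[0] * 10, [1] * 2 + [0] * 8], float)  # distance 0.2
        pi = np.array([[0.6, 0.4]])
        g2, _ = dereplicate(g, pi, threshold=0.05)
        assert g2.shape[0] == 2

    def test_matches_bruteforce_average_linkage(self):
        # 5-strain chain: distances grow along the chain; verify the cut
        rng = np.random.default_rng(0)
        G = 60
        base = rng.integers(0, 2, size=G).astype(float)
        strains = [base.copy() for _ in range(5)]
        for k in range(1, 5):
            strains[k] = strains[k - 1].copy()
            flip = rng.choice(G, size=3, replace=False)
            strains[k][flip] = 1 - strains[k][flip]
        g = np.array(strains)
        pi = np.tile(np.full(5, 0.2), (2, 1))
        g2, p2 = dereplicate(g, pi, threshold=0.05)

        # brute-force average linkage with the same threshold
        clusters = [[i] for i in range(5)]

        def dist(a, b):
            return np.mean(
                [np.mean(g[i] != g[j]) for i in a for j in b]
            )

        while True:
            best = None
            for x, y in itertools.combinations(range(len(clusters)), 2):
                d = dist(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
            if best is None or best[0] > 0.05:
                break
            d, x, y = best
            clusters[x] = clusters[x] + clusters[y]
            del clusters[y]
        assert g2.shape[0] == len(clusters)

    def test_majority_tie_goes_to_alternative(self):
        g = np.array([[0.0, 1.0], [1.0, 1.0]])
        pi = np.array([[0.5, 0.5]])
        g2, _ = dereplicate(g, pi, threshold=0.6)  # force a single cluster
        assert g2.shape[0] == 1
        assert g2[0, 0] == 1.0  # 1-1 tie at site 0 -> alternative

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 2, size=(8, 50)).astype(float)
        pi = rng.dirichlet(np.ones(8), size=3)
        g2, p2 = dereplicate(g, pi, threshold=0.1)
        g3, p3 = dereplicate(g2, p2, threshold=0.1)
        np.testing.assert_array_equal(g2, g3)
        np.testing.assert_allclose(p2, p3)


class TestCocluster:
    def test_copied_reference_gives_all_shared(self):
        rng = np.random.default_rng(2)
        ref = rng.integers(0, 2, size=(4, 40)).astype(float)
        cs = cocluster(ref.copy(), ref, threshold=0.15)
        assert set(cs.cluster_category()) == {"shared"}

    def test_everything_distant_gives_singletons(self):
        # rows of an identity-like pattern: pairwise distance 0.5 >> 0.15
        rng = np.random.default_rng(3)
        inf = rng.integers(0, 2, size=(3, 100)).astype(float)
        ref = 1 - inf[::-1]
        cs = cocluster(inf, ref, threshold=0.01)
        assert cs.n_clusters == 6
        tally = cs.category_tally()
        assert tally["inferred-only"] == 3 and tally["reference-only"] == 3

    def test_categories_partition_strains(self):
        rng = np.random.default_rng(4)
        inf = rng.integers(0, 2, size=(5, 60)).astype(float)
        ref = rng.integers(0, 2, size=(7, 60)).astype(float)
        cs = cocluster(inf, ref, threshold=0.4)
        cats = cs.cluster_category()
        sizes = [(cs.cluster == c).sum() for c in range(cs.n_clusters)]
        assert sum(sizes) == 12
        shared = _enrichment_statistic(cs.cluster, cs.source, "shared-strain-count")
        inf_only = _enrichment_statistic(cs.cluster, cs.source, "inferred-only-strain-count")
        ref_only = sum(
            sizes[c] for c in range(cs.n_clusters) if cats[c] == "reference-only"
        )
        assert shared + inf_only + ref_only == 12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cocluster(np.zeros((0, 5)), np.zeros((2, 5)))


class TestPermutationEnrichment:
    def _toy(self):
        # 4 strains in 2 clusters: cluster 0 = {inferred, reference}, cluster 1 = {inferred, inferred}
        return StrainClusterSet(
            cluster=np.array([0, 0, 1, 1]),
            source=np.array(["inferred", "reference", "inferred", "inferred"]),
            consensus=np.zeros((2, 3)),
        )

    def test_p_value_matches_exact_enumeration(self):
        cs = self._toy()
        observed, p = permutation_enrichment(cs, "shared-strain-count", n_perm=9999, seed=0)
        stats = [
            _enrichment_statistic(np.array(perm), cs.source, "shared-strain-count")
            for perm in itertools.permutations(cs.cluster)
        ]
        exact = np.mean([s >= observed for s in stats])
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(p - exact) < 3 * se + 2e-4  # add-one estimator offset

    def test_constant_statistic_gives_p_one(self):
        # all strains inferred: inferred-only count is invariant to shuffling
        cs = StrainClusterSet(
            cluster=np.array([0, 0, 1, 1]),
            source=np.array(["inferred"] * 4),
            consensus=np.zeros((2, 3)),
        )
        _, p = permutation_enrichment(cs, "inferred-only-strain-count", n_perm=199, seed=1)
        assert p == 1.0

    def test_reproducible_and_bounded(self):
        cs = self._toy()
        _, p1 = permutation_enrichment(cs, "shared-strain-count", n_perm=999, seed=3)
        _, p2 = permutation_enrichment(cs, "shared-strain-count", n_perm=999, seed=3)
        assert p1 == p2
        assert 1 / 1000 <= p1 <= 1.0


class TestDominantStrain:
    def test_argmax_and_tie_convention(self):
        pi = np.array([[0.7, 0.2, 0.1], [0.5, 0.5, 0.0], [0.1, 0.2, 0.7]])
        np.testing.assert_array_equal(dominant_strain(pi), [0, 0, 2])


class TestPairwiseLD:
    def test_perfect_and_zero_linkage(self):
        g = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], float)  # identical columns
        assert pairwise_ld(g, [(0, 1)])[0] == pytest.approx(1.0)
        g = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)  # orthogonal
        assert pairwise_ld(g, [(0, 1)])[0] == pytest.approx(0.0)

    def test_monomorphic_pair_is_missing(self):
        g = np.array([[0, 0], [0, 1], [0, 0]], float)
        assert np.isnan(pairwise_ld(g, [(0, 1)])[0])

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 2, size=(20, 6)).astype(float)
        pairs = list(itertools.combinations(range(6), 2))
        out = pairwise_ld(g, pairs)
        for (a, b), val in zip(pairs, out):
            x, y = g[:, a], g[:, b]
            if x.std() == 0 or y.std() == 0:
                assert np.isnan(val)
            else:
                assert val == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_symmetric_and_allele_flip_invariant(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 2, size=(15, 2)).astype(float)
        r_ab = pairwise_ld(g, [(0, 1)])[0]
        r_ba = pairwise_ld(g, [(1, 0)])[0]
        flipped = g.copy()
        flipped[:, 0] = 1 - flipped[:, 0]
        r_flip = pairwise_ld(flipped, [(0, 1)])[0]
        assert r_ab == pytest.approx(r_ba)
        assert r_ab == pytest.approx(r_flip)


class TestGenomewideLD90:
    def test_perfectly_linked_sites(self):
        col = np.array([0, 0, 1, 1, 0, 1], float)
        g = np.tile(col[:, None], (1, 8))  # identical columns: all pairs r^2 = 1
        assert genomewide_ld90(g, np.arange(1, 9)) == pytest.approx(1.0)

    def test_independent_genotypes_match_null_simulation(self):
        rng = np.random.default_rng(7)
        S, G = 60, 40
        g = rng.integers(0, 2, size=(S, G)).astype(float)
        obs = genomewide_ld90(g, np.arange(1, G + 1), seed=0)
        # direct null simulation of the r^2 90th percentile
        null = []
        for rep in range(30):
            h = np.random.default_rng(100 + rep).integers(0, 2, size=(S, G)).astype(float)
            null.append(genomewide_ld90(h, np.arange(1, G + 1), seed=0))
        assert abs(obs - np.mean(null)) < 5 * np.std(null)

    def test_subsampling_reproducible(self):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 2, size=(10, 300)).astype(float)
        pos = np.arange(1, 301)
        a = genomewide_ld90(g, pos, max_positions=100, seed=3)
        b = genomewide_ld90(g, pos, max_positions=100, seed=3)
        assert a == b


class TestLDDecayProfile:
    def test_window_scheme_c30_has_120_windows(self):
        windows = ld_windows(c=30, max_distance=10_000)
        assert len(windows) == 120
        assert windows[0][0] == 1
        assert windows[-1][1] == 10_000

    def test_window_bounds_follow_floor_formula(self):
        windows = ld_windows(c=30)
        i = 120
        assert windows[i - 1] == (
            int(np.floor(10 ** ((i - 1) / 30))),
            int(np.floor(10 ** (i / 30))),
        )

    def test_block_structure_recovered(self):
        # perfect LD within 100-bp blocks, independent across blocks
        rng = np.random.default_rng(9)
        S = 40
        n_blocks, per_block = 30, 5
        cols, pos = [], []
        p = 1
        for b in range(n_blocks):
            anchor = rng.integers(0, 2, size=S).astype(float)
            for k in range(per_block):
                cols.append(anchor)
                pos.append(p)
                p += 20  # sites 20 bp apart within a 100-bp block
            p += 5000  # big gap between blocks
        g = np.array(cols).T
        profile = ld_decay_profile(g, np.array(pos), c=30, max_distance=10_000)
        close = [
            v for (lo, hi), v in zip(profile.windows, profile.ld90)
            if hi <= 100 and np.isfinite(v)
        ]
        far = [
            v for (lo, hi), v in zip(profile.windows, profile.ld90)
            if lo > 1000 and np.isfinite(v)
        ]
        assert min(close) == pytest.approx(1.0)
        assert max(far) < 0.5
        assert profile.adjacent_ld90 == pytest.approx(1.0)
        assert profile.ld_half_90 > 100

    def test_pairs_partition_across_windows(self):
        rng = np.random.default_rng(10)
        g = rng.integers(0, 2, size=(12, 40)).astype(float)
        pos = np.sort(rng.choice(5000, size=40, replace=False)) + 1
        profile = ld_decay_profile(g, pos, c=30, max_distance=10_000)
        n_pairs_in_range = sum(
            1
            for i, j in itertools.combinations(range(40), 2)
            if abs(pos[j] - pos[i]) <= profile.windows[-1][1]
        )
        assert profile.pair_counts.sum() == n_pairs_in_range
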