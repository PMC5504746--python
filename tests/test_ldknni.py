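"""LD computation, neighbour tables, distances and kNN imputation."""

import numpy as np
import pytest

from gbsimpute.ldknni import (MISSING, ImputationImpossibleError, KnnParams,
                              build_neighbour_table, distances_to_all,
                              impute_distribution, known_genotype_matrix,
                              ld_matrix, optimize_k_l, pairwise_ld,
                              sample_distance)

from conftest import make_matrix


def naive_r2(genotypes, a, b):
    """Brute-force pairwise-complete squared Pearson correlation."""
    pairs = [(x, y) for x, y in zip(genotypes[:, a], genotypes[:, b])
             if x != MISSING and y != MISSING]
    if len(pairs) < 2:
        return 0.0
    x = np.array([p[0] for p in pairs], float)
    y = np.array([p[1] for p in pairs], float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def naive_impute(genotypes, a, b, k, l):
    """Reference LD-kNN imputation: full recomputation, no caching.

    Recomputes the LD row of site ``a`` pair by pair, picks the top-l
    sites, measures every sample's distance directly, and votes.
    """
    n_samples, n_sites = genotypes.shape
    r2 = [(pairwise_ld(genotypes, a, c), -c) for c in range(n_sites) if c != a]
    lsites = [-c for _, c in sorted(r2, key=lambda t: t, reverse=True)[:l]]
    scored = []
    for s in range(n_samples):
        if s == b or genotypes[s, a] == MISSING:
            continue
        usable = [(genotypes[b, c], genotypes[s, c]) for c in lsites
                  if genotypes[b, c] != MISSING and genotypes[s, c] != MISSING]
        if not usable:
            d = 1.0 + 2.0 * l
        else:
            manh = sum(abs(int(x) - int(y)) for x, y in usable)
            d = 1.0 + manh * (l / len(usable))
        scored.append((d, s))
    scored.sort()
    c = np.zeros(3)
    for d, s in scored[:k]:
        c[genotypes[s, a]] += 1.0 / d
    return c / c.sum()


def random_genotypes(rng, n_samples, n_sites, missing_frac=0.2):
    g = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    g[rng.random((n_samples, n_sites)) < missing_frac] = MISSING
    return g


class TestPairwiseLD:
    def test_identical_vectors_give_one(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8)
        assert pairwise_ld(g, 0, 1) == pytest.approx(1.0)

    def test_one_flip_matches_direct_pearson(self):
        x = np.array([0, 1, 2, 1, 0, 2])
        y = x.copy()
        y[2] = 0  # flip one homozygote
        g = np.stack([x, y], axis=1).astype(np.int8)
        expect = float(np.corrcoef(x, y)[0, 1] ** 2)
        assert pairwise_ld(g, 0, 1) == pytest.approx(expect)

    def test_constant_site_gives_zero(self):
        g = np.array([[1, 0], [1, 1], [1, 2]], dtype=np.int8)
        assert pairwise_ld(g, 0, 1) == 0.0

    def test_fewer_than_two_complete_pairs_gives_zero(self):
        g = np.array([[0, MISSING], [MISSING, 1], [2, 0]], dtype=np.int8)
        assert pairwise_ld(g, 0, 1) == 0.0

    def test_ld_matrix_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        g = random_genotypes(rng, 12, 15)
        mat = ld_matrix(g)
        for a in range(15):
            for b in range(15):
                expect = 0.0 if a == b else naive_r2(g, a, b)
                assert mat[a, b] == pytest.approx(expect, abs=1e-10)


class TestNeighbourTable:
    def test_dominant_partner_selected(self):
        g = np.array([[0, 0, 0], [1, 1, 2], [2, 2, 0], [1, 1, 2], [0, 0, 2]],
                     dtype=np.int8)
        table = build_neighbour_table(g, 1)
        assert table.neighbours[0, 0] == 1  # r2(0,1)=1 beats r2(0,2)

    def test_all_equal_r2_ties_to_lowest_indices(self):
        g = np.tile(np.array([[0], [1], [2], [1]], dtype=np.int8), (1, 4))
        table = build_neighbour_table(g, 2)
        assert table.neighbours[0].tolist() == [1, 2]
        assert table.neighbours[3].tolist() == [0, 1]

    def test_matches_full_sort_oracle(self):
        # the r^2 values themselves are checked against brute force in
        # test_ld_matrix_matches_bruteforce; here the top-l selection and
        # index tie-break are checked against a full sort of those values
        rng = np.random.default_rng(3)
        g = random_genotypes(rng, 15, 20)
        r2 = ld_matrix(g)
        table = build_neighbour_table(g, 5)
        for a in range(20):
            pairs = sorted(((r2[a, b], -b) for b in range(20) if b != a),
                           reverse=True)
            expect = [-b for _, b in pairs[:5]]
            assert table.neighbours[a].tolist() == expect

    def test_r2_values_non_increasing(self):
        rng = np.random.default_rng(4)
        g = random_genotypes(rng, 20, 25)
        table = build_neighbour_table(g, 8)
        assert (np.diff(table.r2, axis=1) <= 1e-12).all()

    def test_l_too_large_rejected(self):
        g = np.zeros((4, 3), dtype=np.int8)
        with pytest.raises(ValueError):
            build_neighbour_table(g, 3)


class TestSampleDistance:
    def _fixture(self):
        # site 0 is the target; sites 1,2 are its LD partners
        g = np.array([
            [0, 2, 1],
            [1, 0, 0],
            [2, 2, 1],
            [MISSING, MISSING, MISSING],
        ], dtype=np.int8)
        table = build_neighbour_table(g, 2)
        return g, table

    def test_identical_samples_distance_one(self):
        g, table = self._fixture()
        assert sample_distance(g, table, 0, 0, 2) == pytest.approx(1.0)

    def test_manhattan_sum_plus_offset(self):
        g, table = self._fixture()
        # samples 0 and 1 differ by (2,1) on the two LD sites -> 1 + 3
        assert sample_distance(g, table, 0, 0, 1) == pytest.approx(4.0)

    def test_rescaling_with_partial_overlap(self):
        # l=4 but only 2 usable sites differing by (1,0) -> 1 + 1*(4/2) = 3
        g = np.array([
            [0, 1, 0, MISSING, MISSING],
            [1, 0, 0, 1, 2],
            [0, 1, 0, 1, 2],
            [2, 0, 2, 0, 0],
            [1, 2, 1, 2, 1],
            [0, 0, 1, 1, 0],
        ], dtype=np.int8)
        table = build_neighbour_table(g, 4)
        lsites = table.neighbours[0]
        usable = [c for c in lsites if g[0, c] != MISSING]
        manh = sum(abs(int(g[0, c]) - int(g[1, c])) for c in usable)
        expect = 1 + manh * (4 / len(usable))
        assert sample_distance(g, table, 0, 0, 1) == pytest.approx(expect)

    def test_no_usable_sites_is_maximal(self):
        g, table = self._fixture()
        assert sample_distance(g, table, 0, 3, 1) == pytest.approx(1 + 2 * 2)

    def test_self_distance_rejected(self):
        g, table = self._fixture()
        with pytest.raises(ValueError):
            sample_distance(g, table, 0, 1, 1)


class TestImputeDistribution:
    def test_single_neighbour_certainty(self):
        g = np.array([[MISSING, 1, 1], [2, 1, 1], [MISSING, 0, 0]], dtype=np.int8)
        table = build_neighbour_table(g, 2)
        dist = impute_distribution(g, table, KnnParams(1, 2), 0, 0)
        assert dist == pytest.approx([0, 0, 1])

    def test_weighted_two_neighbour_vote(self):
        # neighbours at distances 1 and 4 carrying genotypes 0 and 1:
        # c = (1, 0.25, 0) -> p = (0.8, 0.2, 0)
        g = np.array([
            [MISSING, 0, 2],
            [0, 0, 2],
            [1, 2, 1],
        ], dtype=np.int8)
        table = build_neighbour_table(g, 2)
        d1 = sample_distance(g, table, 0, 0, 1)
        d2 = sample_distance(g, table, 0, 0, 2)
        assert (d1, d2) == (1.0, 4.0)
        dist = impute_distribution(g, table, KnnParams(2, 2), 0, 0)
        assert dist == pytest.approx([0.8, 0.2, 0])

    def test_neighbour_shortage_uses_what_exists(self):
        g = np.array([
            [MISSING, 0, 2],
            [0, 0, 2],
            [1, 2, 1],
        ], dtype=np.int8)
        table = build_neighbour_table(g, 2)
        d3 = impute_distribution(g, table, KnnParams(3, 2), 0, 0)
        d2 = impute_distribution(g, table, KnnParams(2, 2), 0, 0)
        assert d3 == pytest.approx(d2)

    def test_no_informative_sample_raises(self):
        g = np.array([[MISSING, 1], [MISSING, 0], [MISSING, 2]], dtype=np.int8)
        table = build_neighbour_table(g, 1)
        with pytest.raises(ImputationImpossibleError):
            impute_distribution(g, table, KnnParams(1, 1), 0, 0)

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            g = random_genotypes(rng, 15, 30)
            a = int(rng.integers(30))
            known_at_a = np.flatnonzero(g[:, a] != MISSING)
            if known_at_a.size < 2:
                continue
            b = int(known_at_a[0])
            k = int(rng.integers(1, 8))
            l = int(rng.integers(1, 12))
            table = build_neighbour_table(g, l)
            got = impute_distribution(g, table, KnnParams(k, l), a, b)
            np.testing.assert_allclose(got, naive_impute(g, a, b, k, l), atol=1e-12)

    def test_output_is_distribution(self):
        rng = np.random.default_rng(23)
        g = random_genotypes(rng, 12, 20)
        table = build_neighbour_table(g, 6)
        for a in range(20):
            if (g[:, a] != MISSING).sum() < 2:
                continue
            dist = impute_distribution(g, table, KnnParams(4, 6), a, 0)
            assert (dist >= 0).all()
            assert dist.sum() == pytest.approx(1.0)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(31)
        g = random_genotypes(rng, 10, 20, missing_frac=0.1)
        # jitter to avoid distance ties, which legitimately depend on order
        table = build_neighbour_table(g, 5)
        perm = rng.permutation(10)
        gp = g[perm]
        table_p = build_neighbour_table(gp, 5)
        inv = np.argsort(perm)
        for a in range(20):
            b = 0
            if g[b, a] == MISSING or (g[:, a] != MISSING).sum() < 3:
                continue
            d1 = distances_to_all(g, table, a, b)
            d2 = distances_to_all(gp, table_p, a, int(inv[b]))
            if len(np.unique(np.round(d1, 9))) < len(d1):
                continue  # tie case excluded by construction
            p1 = impute_distribution(g, table, KnnParams(3, 5), a, b)
            p2 = impute_distribution(gp, table_p, KnnParams(3, 5), a, int(inv[b]))
            np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestOptimizeKL:
    def test_single_candidate_grid(self):
        g = np.array([[0, 0, 1], [0, 0, 1], [2, 2, 0], [2, 2, 0]], dtype=np.int8)
        params = optimize_k_l(g, [(0, 0, 0)], k_grid=[1], l_grid=[1])
        assert (params.k, params.l) == (1, 1)

    def test_duplicated_samples_perfect_with_k1(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        g = np.repeat(base, 2, axis=0)  # every sample has an exact clone
        training = [(int(a), int(b), int(g[b, a]))
                    for a, b in zip(rng.integers(0, 30, 20), rng.integers(0, 16, 20))]
        table = build_neighbour_table(g, 8)
        correct = 0
        for a, b, known in training:
            dist = impute_distribution(g, table, KnnParams(1, 8), a, b)
            correct += int(np.argmax(dist) == known)
        assert correct == len(training)

    def test_ties_prefer_smaller_l_then_k(self):
        base = np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8)
        g = np.repeat(base, 2, axis=0)
        # duplicated samples: every grid point is perfect -> smallest (l, k)
        training = [(0, 0, 0), (1, 2, 2)]
        params = optimize_k_l(g, training, k_grid=[1, 2, 3], l_grid=[1])
        assert (params.k, params.l) == (1, 1)

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(55)
        # LD confined to 5-site blocks: duplicate each block's pattern
        block = rng.integers(0, 3, size=(20, 8)).astype(np.int8)
        g = np.repeat(block, 5, axis=1)
        g[rng.random(g.shape) < 0.2] = MISSING
        training = []
        for _ in range(25):
            a, b = int(rng.integers(40)), int(rng.integers(20))
            if g[b, a] != MISSING:
                training.append((a, b, int(g[b, a])))
        k_grid, l_grid = [1, 2, 4], [2, 4, 8]
        params = optimize_k_l(g, training, k_grid, l_grid)
        # brute force with the naive reference implementation
        best, best_key = None, None
        for l in l_grid:
            for k in k_grid:
                acc = sum(int(np.argmax(naive_impute(g, a, b, k, l)) == known)
                          for a, b, known in training)
                key = (acc, -l, -k)
                if best_key is None or key > best_key:
                    best_key, best = key, (k, l)
        assert (params.k, params.l) == best

    def test_empty_training_rejected(self):
        g = np.zeros((4, 4), dtype=np.int8)
        with pytest.raises(ValueError):
            optimize_k_l(g, [])


class TestKnownGenotypeMatrix:
    def test_depth_threshold_respected(self):
        m = make_matrix([[10, 3], [0, 40]], [[0, 2], [0, 0]])
        g = known_genotype_matrix(m, d=8)
        assert g[0, 0] == 0       # depth 10 > 8: inferred
        assert g[0, 1] == MISSING  # depth 5 <= 8
        assert g[1, 0] == MISSING  # depth 0
        assert g[1, 1] == 0
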