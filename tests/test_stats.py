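"""Community statistics against closed forms, brute force and scikit-bio."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from coimeta.stats import (DistanceMatrix, accumulation_curves, alpha_stats,
                           anova_blocked, bray_curtis, chao_similarity,
                           expected_richness_reads, expected_richness_samples,
                           group_comparison, hellinger_distance,
                           hellinger_transform, pcoa, permanova, simper,
                           ttest_two_groups)


class TestHellinger:
    def test_examples(self):
        out = hellinger_transform(np.array([[4, 0, 0]]))
        assert np.allclose(out, [[1, 0, 0]])
        out = hellinger_transform(np.array([[1, 1, 1, 1]]))
        assert np.allclose(out, [[0.5] * 4])

    def test_rows_unit_norm(self, rng):
        y = rng.poisson(3, size=(5, 8)) + 1
        h = hellinger_transform(y).to_numpy()
        assert np.allclose((h ** 2).sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_dropped_or_error(self):
        y = np.array([[1, 2], [0, 0]])
        with pytest.warns(UserWarning):
            h = hellinger_transform(y)
        assert h.shape[0] == 1
        with pytest.raises(ValueError):
            hellinger_transform(y, on_zero_rows="error")


class TestBrayCurtis:
    def test_examples(self):
        y = np.array([[1, 2, 3], [3, 2, 1]])
        d = bray_curtis(y)
        assert d.values[0, 1] == pytest.approx(4 / 12)
        same = bray_curtis(np.array([[1, 2], [1, 2]]))
        assert same.values[0, 1] == 0
        disjoint = bray_curtis(np.array([[5, 0], [0, 7]]))
        assert disjoint.values[0, 1] == 1

    def test_range_and_zero_pair(self, rng):
        y = rng.poisson(2, size=(6, 10))
        d = bray_curtis(y).values
        assert ((0 <= d) & (d <= 1)).all()
        with pytest.warns(UserWarning):
            dz = bray_curtis(np.array([[0, 0], [0, 0], [1, 1]]))
        assert dz.values[0, 1] == 0


class TestPcoa:
    def test_reproduces_euclidean_embedding(self, rng):
        pts = rng.normal(size=(7, 2))
        from scipy.spatial import distance_matrix as sdm
        D = sdm(pts, pts)
        res = pcoa(DistanceMatrix(D, list(range(7)), "euclidean"))
        C = res.coordinates.to_numpy()
        D2 = sdm(C, C)
        assert np.allclose(D, D2, atol=1e-9)
        assert res.negative_eigenvalues.size == 0

    def test_equidistant_simplex_spectrum(self):
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        res = pcoa(DistanceMatrix(D, list("abcd"), "toy"))
        assert res.eigenvalues.size == 3
        assert np.allclose(res.eigenvalues, res.eigenvalues[0])

    def test_non_euclidean_reports_negative_eigenvalue(self):
        # 0-1 at distance 2, both midpoints -> metrically impossible in R^n
        D = np.array([
            [0, 2, 1, 1],
            [2, 0, 1, 1],
            [1, 1, 0, 2],
            [1, 1, 2, 0],
        ], dtype=float)
        res = pcoa(DistanceMatrix(D, list("abcd"), "toy"))
        assert res.negative_eigenvalues.size > 0
        assert (res.eigenvalues > 0).all()

    def test_small_n_errors(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(D, ["a", "b"], "x"))


def _brute_F(D, codes):
    """Textbook pseudo-F computed with plain loops."""
    N = len(codes)
    a = len(set(codes))
    ss_t = sum(D[i, j] ** 2 for i in range(N) for j in range(i + 1, N)) / N
    ss_w = 0.0
    for g in set(codes):
        idx = [i for i in range(N) if codes[i] == g]
        ss_w += sum(D[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (N - a))


class TestPermanova:
    def test_matches_scikit_bio(self, rng):
        y = rng.poisson(20, size=(10, 8)).astype(float)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        dm = hellinger_distance(y)
        mine = permanova(dm, groups, n_perm=999, seed=1)
        import skbio
        from skbio.stats.distance import permanova as sk_permanova
        sk = sk_permanova(skbio.DistanceMatrix(dm.values), list(groups),
                          permutations=999)
        assert mine.pseudo_F == pytest.approx(sk["test statistic"], rel=1e-10)
        assert 0 <= mine.R_squared <= 1
        assert mine.p_value >= 1 / 1000

    def test_exhaustive_matches_bruteforce_at_n6(self, rng):
        pts = rng.normal(size=(6, 3))
        from scipy.spatial import distance_matrix as sdm
        D = sdm(pts, pts)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        dm = DistanceMatrix(D, list(range(6)), "euclidean")
        res = permanova(dm, groups, exhaustive=True, return_perm_F=True)
        assert res.n_permutations == 720
        codes = (groups == "b").astype(int)
        brute = sorted(
            _brute_F(D, codes[list(p)]) for p in
            itertools.permutations(range(6))
        )
        assert np.allclose(sorted(res.perm_F), brute, atol=1e-10)
        brute_p = np.mean(np.array(brute) >= res.pseudo_F - 1e-12)
        assert res.p_value == pytest.approx(brute_p)

    def test_separated_clusters_reach_minimal_p(self, rng):
        # groups of 10 so no random permutation recreates the partition
        y = np.vstack([rng.normal(0, 0.05, size=(10, 3)),
                       rng.normal(5, 0.05, size=(10, 3))])
        from scipy.spatial import distance_matrix as sdm
        D = sdm(y, y)
        dm = DistanceMatrix(D, list(range(20)), "euclidean")
        res = permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=0,
                        return_perm_F=True)
        # observed F beats every permutation except exact recreations of the
        # partition (F ties), so p attains (ties+1)/(n_perm+1)
        ties = int(np.count_nonzero(res.perm_F >= res.pseudo_F - 1e-12))
        assert np.all(res.perm_F <= res.pseudo_F + 1e-9)
        assert res.p_value == pytest.approx((ties + 1) / 1000)
        assert res.p_value <= 5 / 1000

    def test_degenerate_group_errors(self, rng):
        D = np.zeros((4, 4))
        dm = DistanceMatrix(D, list(range(4)), "x")
        with pytest.raises(ValueError, match="degenerate"):
            permanova(dm, ["a", "b", "b", "b"])

    def test_seed_reproducible(self, rng):
        y = rng.poisson(5, size=(8, 6)).astype(float)
        dm = hellinger_distance(y + 1)
        g = ["a"] * 4 + ["b"] * 4
        p1 = permanova(dm, g, seed=5).p_value
        p2 = permanova(dm, g, seed=5).p_value
        assert p1 == p2


class TestSimper:
    def test_single_species_differs(self):
        y = pd.DataFrame({"sp1": [5, 5, 0, 0], "sp2": [3, 3, 3, 3]})
        tab = simper(y, ["a", "a", "b", "b"])
        assert tab.iloc[0]["species"] == "sp1"
        assert tab.iloc[0]["percent"] == pytest.approx(100.0)

    def test_conservation_on_random_matrices(self, rng):
        for _ in range(5):
            y = rng.poisson(4, size=(7, 9)).astype(float) + 0.1
            g = np.array(["a"] * 3 + ["b"] * 4)
            tab = simper(y, g)
            total = tab["average_contribution"].sum()
            bc = bray_curtis(y).values
            between = bc[np.ix_(np.flatnonzero(g == "a"),
                                np.flatnonzero(g == "b"))]
            assert total == pytest.approx(between.mean(), abs=1e-10)
            assert tab["cumulative_percent"].iloc[-1] == pytest.approx(100.0)

    def test_tied_contributors_split_evenly_stable_order(self):
        y = pd.DataFrame({"b_sp": [2, 2, 0, 0], "a_sp": [0, 0, 2, 2]})
        tab = simper(y, ["a", "a", "b", "b"])
        assert list(tab["percent"].round(9)) == [50.0, 50.0]
        assert list(tab["species"]) == ["a_sp", "b_sp"]  # name breaks tie


class TestAlpha:
    def test_closed_forms(self):
        uniform = np.ones((1, 10)) * 7
        out = alpha_stats(uniform)
        assert out["shannon"][0] == pytest.approx(math.log(10), abs=1e-12)
        single = np.array([[9, 0, 0]])
        assert alpha_stats(single)["shannon"][0] == pytest.approx(0.0)
        counts = np.array([[5, 3, 2]])
        expect = -(0.5 * math.log(0.5) + 0.3 * math.log(0.3)
                   + 0.2 * math.log(0.2))
        assert alpha_stats(counts)["shannon"][0] == pytest.approx(expect,
                                                                  abs=1e-9)

    def test_zero_sample_missing(self):
        out = alpha_stats(np.array([[0, 0], [1, 1]]))
        assert np.isnan(out["shannon"][0]) and out["richness"][0] == 0

    def test_bounds(self, rng):
        y = rng.poisson(3, size=(6, 12))
        out = alpha_stats(y)
        ok = out["reads"] > 0
        assert (out.loc[ok, "shannon"]
                <= np.log(out.loc[ok, "richness"].clip(lower=1)) + 1e-12).all()


class TestAccumulation:
    def test_endpoint_equals_observed_richness(self, rng):
        y = rng.poisson(2, size=(5, 12))
        y[:, 0] += 1  # guarantee at least one species
        S_obs = int(((y.sum(axis=0)) > 0).sum())
        assert expected_richness_samples(y, 5) == pytest.approx(S_obs)
        N = int(y.sum())
        assert expected_richness_reads(y.sum(axis=0), N) == pytest.approx(S_obs)
        assert expected_richness_reads(y.sum(axis=0), 1) == pytest.approx(1.0)

    def test_exhaustive_subset_average_three_samples(self):
        y = np.array([[3, 0, 1], [0, 2, 1], [4, 4, 0]])
        got = expected_richness_samples(y, 2)
        subsets = list(itertools.combinations(range(3), 2))
        brute = np.mean([((y[list(s)].sum(axis=0)) > 0).sum() for s in subsets])
        assert got == pytest.approx(brute, abs=1e-12)

    def test_monotone_and_envelopes(self, rng):
        y = rng.poisson(3, size=(6, 15))
        curves = accumulation_curves(y, n_boot=50, seed=1)
        for key in ("sample_based", "read_based"):
            e = curves[key]["expected_richness"].to_numpy()
            assert (np.diff(e) >= -1e-9).all()
            assert (curves[key]["lo"] <= curves[key]["hi"]).all()

    def test_out_of_range_errors(self):
        y = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            expected_richness_samples(y, 3)
        with pytest.raises(ValueError):
            expected_richness_reads(y.sum(axis=0), 10)


class TestChaoSimilarity:
    def test_identical_assemblages(self):
        x = np.array([5, 3, 2])
        est = chao_similarity(x, x)
        assert est.U == est.V == 1.0
        assert est.chao_jaccard == est.chao_sorensen == 1.0
        assert est.jaccard == est.sorensen == 1.0

    def test_disjoint_assemblages(self):
        est = chao_similarity([3, 0, 2, 0], [0, 4, 0, 1])
        assert est.chao_jaccard == est.chao_sorensen == 0.0

    def test_hand_evaluated_fixture(self):
        # x=(10,2,1,0), y=(5,1,0,3): shared = {0,1}; n=13, m=9
        # U = 12/13 + (8/9)(1/2)(2/13) = 116/117;  V = 6/9 (no x-singletons shared)
        est = chao_similarity([10, 2, 1, 0], [5, 1, 0, 3])
        assert est.U == pytest.approx(116 / 117, abs=1e-12)
        assert est.V == pytest.approx(2 / 3, abs=1e-12)
        assert est.chao_jaccard == pytest.approx(232 / 350, abs=1e-12)
        assert est.chao_sorensen == pytest.approx(232 / 291, abs=1e-12)
        assert est.jaccard == pytest.approx(2 / 4)
        assert est.sorensen == pytest.approx(4 / 6)

    def test_bounds_and_sorensen_ge_jaccard(self, rng):
        for _ in range(30):
            x = rng.poisson(1.5, 12)
            y = rng.poisson(1.5, 12)
            est = chao_similarity(x, y)
            for v in (est.U, est.V, est.chao_jaccard, est.chao_sorensen,
                      est.jaccard, est.sorensen):
                assert -1e-12 <= v <= 1 + 1e-12
            assert est.sorensen >= est.jaccard - 1e-12
            assert est.chao_sorensen >= est.chao_jaccard - 1e-12

    def test_same_community_estimates_approach_one(self, rng):
        p = rng.dirichlet(np.ones(30))
        x = rng.multinomial(5000, p)
        y = rng.multinomial(5000, p)
        est = chao_similarity(x, y)
        assert est.chao_sorensen > 0.95 and est.chao_jaccard > 0.9


class TestGroupComparison:
    def test_textbook_pooled_t(self):
        res = ttest_two_groups([3, 4, 5, 7, 8, 9],
                               ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == pytest.approx(-4.898979, abs=1e-5)
        assert res.df == (4,)

    def test_equal_groups_t_near_zero(self, rng):
        v = np.concatenate([rng.normal(0, 1, 400), rng.normal(0, 1, 400)])
        g = ["a"] * 400 + ["b"] * 400
        res = ttest_two_groups(v, g)
        assert abs(res.statistic) < 2.5 and res.p_value > 0.01

    def test_block_only_effect_keeps_type_one_error(self, rng):
        # no treatment effect, strong block effect: F ~ F(1, .), alpha ~ 5%
        rej = 0
        n_sims = 300
        for i in range(n_sims):
            r = np.random.default_rng(i)
            block_eff = r.normal(0, 3, 6)
            y, g, b = [], [], []
            for blk in range(6):
                for trt in ("a", "b"):
                    y.append(block_eff[blk] + r.normal())
                    g.append(trt)
                    b.append(str(blk))
            res = anova_blocked(y, g, blocks=b)
            rej += res.p_value <= 0.05
        assert 0.02 <= rej / n_sims <= 0.09

    def test_dispatch_and_log10(self):
        res = group_comparison([10, 100, 1000, 10, 100, 1000],
                               ["a", "a", "a", "b", "b", "b"], log10=True)
        assert res.method == "student_t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        res2 = group_comparison([1, 2, 3, 4, 5, 6],
                                ["a", "a", "b", "b", "c", "c"])
        assert res2.method == "anova"
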