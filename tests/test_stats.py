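import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal as scipy_kruskal
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from blankgate.stats import (kruskal_stress, kruskal_wallis, nmds, ols_r2,
                             permanova, ss_decomposition, _disparities)

from oracles import kruskal_h_bf, ols_bf, pav_bf, permanova_ss_bf


def random_distance_matrix(rng, n):
    pts = rng.uniform(size=(n, 3))
    return DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(n)])


class TestOls:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = ols_r2(x, 2 * x + 1)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_y_gives_zero(self):
        assert ols_r2(np.arange(4.0), np.full(4, 3.0)).r2 == 0.0

    def test_matches_correlation_squared_oracle(self, rng):
        x = rng.uniform(size=40)
        y = x + rng.normal(0, 5, size=40)
        res = ols_r2(x, y)
        r2_bf, slope_bf, intercept_bf = ols_bf(list(x), list(y))
        assert res.r2 == pytest.approx(r2_bf, abs=1e-12)
        assert res.slope == pytest.approx(slope_bf, rel=1e-12)
        assert res.intercept == pytest.approx(intercept_bf, rel=1e-12)

    def test_degenerate_x_is_error(self):
        with pytest.raises(ValueError):
            ols_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKruskalWallis:
    def test_hand_rank_arithmetic(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.H_statistic == pytest.approx(27 / 7, abs=1e-9)  # 3.857
        assert res.df == 1

    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.H_statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_with_and_without_ties(self, rng):
        for _ in range(20):
            values = np.round(rng.normal(size=18), 1)  # rounding makes ties
            groups = rng.choice(["a", "b", "c"], size=18)
            if len(set(groups)) < 2:
                continue
            res = kruskal_wallis(values, groups)
            ref = scipy_kruskal(*(values[groups == g] for g in set(groups)))
            assert res.H_statistic == pytest.approx(ref.statistic, rel=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_untied_equals_tie_corrected_form(self, rng):
        values = rng.permutation(np.arange(12.0))
        groups = np.repeat(["a", "b", "c"], 4)
        res = kruskal_wallis(values, groups)
        assert res.H_statistic == pytest.approx(
            kruskal_h_bf(list(values), list(groups)), rel=1e-9)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestPermanova:
    def worked_example(self):
        # two tight pairs far apart: within-pair d = 0.1, across = 1.0
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
        return DistanceMatrix(d, ids=list("wxyz")), ["g1", "g1", "g2", "g2"]

    def test_worked_example_f_and_exhaustive_p(self):
        dm, groups = self.worked_example()
        res = permanova(dm, groups, exhaustive=True)
        assert res.pseudo_F == pytest.approx(199.0, rel=1e-9)
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_ss_decomposition_matches_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 12))
            dm = random_distance_matrix(rng, n)
            groups = list(rng.choice(["a", "b", "c"], size=n))
            if len(set(groups)) < 2:
                continue
            ss = ss_decomposition(dm, groups)
            bf = permanova_ss_bf(dm.data.tolist(), groups)
            assert np.allclose(ss, bf, rtol=1e-9)

    def test_pseudo_f_matches_skbio(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            dm = random_distance_matrix(local, 12)
            groups = list(local.choice(["a", "b"], size=12))
            if len(set(groups)) < 2:
                continue
            res = permanova(dm, groups, n_permutations=9, seed=0)
            ref = skbio_permanova(dm, grouping=groups, permutations=9)
            assert res.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_exhaustive_agrees_with_sampled(self, rng):
        dm = random_distance_matrix(rng, 8)
        groups = ["a"] * 4 + ["b"] * 4
        exact = permanova(dm, groups, exhaustive=True)
        sampled = permanova(dm, groups, n_permutations=999, seed=1)
        assert abs(exact.p_value - sampled.p_value) <= 2 / np.sqrt(999)

    def test_invariant_to_relabeling_and_reordering(self, rng):
        dm = random_distance_matrix(rng, 10)
        groups = pd.Series(list("aabbbababa"), index=dm.ids)
        base = permanova(dm, groups, n_permutations=99, seed=0)
        renamed = permanova(dm, groups.map({"a": "x", "b": "y"}),
                            n_permutations=99, seed=0)
        assert renamed.pseudo_F == pytest.approx(base.pseudo_F, rel=1e-12)
        order = list(rng.permutation(dm.ids))
        reordered = permanova(dm.filter(order), groups.loc[order],
                              n_permutations=99, seed=0)
        assert reordered.pseudo_F == pytest.approx(base.pseudo_F, rel=1e-9)

    def test_p_value_floor(self, rng):
        dm = random_distance_matrix(rng, 10)
        res = permanova(dm, ["a"] * 5 + ["b"] * 5, n_permutations=99, seed=0)
        assert res.p_value >= 1 / 100
        assert 0 <= res.r2 <= 1

    def test_single_group_is_error(self, rng):
        dm = random_distance_matrix(rng, 5)
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 5)


class TestIsotonic:
    def test_matches_hand_rolled_pav(self, rng):
        for _ in range(30):
            e = rng.normal(size=25)
            d = np.sort(rng.uniform(size=25))  # already-ordered dissimilarities
            fit = _disparities(e, d)
            assert np.allclose(fit, pav_bf(list(e)), atol=1e-12)


class TestNmds:
    def test_exact_euclidean_configuration_is_recovered(self):
        # 4 corners of a rectangle: perfectly embeddable in 2-D
        pts = np.array([[0, 0], [1, 0], [0, 2], [1, 2]], dtype=float)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = nmds(dm, k=2, n_starts=10, seed=0)
        assert res.stress < 1e-3

    def test_collinear_three_points(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        dm = DistanceMatrix(d, ids=list("abc"))
        res = nmds(dm, k=2, n_starts=10, seed=0)
        assert res.stress < 1e-3

    def test_stress_decreases_within_a_start(self, rng):
        # a random metric on 5 points is generally not 2-D embeddable
        dm = random_distance_matrix(rng, 5)
        res = nmds(dm, k=2, n_starts=1, seed=4)
        diffs = np.diff(res.trajectory)
        assert len(res.trajectory) > 2
        assert (diffs < 1e-7).all()

    def test_stress_self_consistency(self, rng):
        dm = random_distance_matrix(rng, 8)
        res = nmds(dm, k=2, n_starts=5, seed=0)
        assert kruskal_stress(dm, res.coordinates) == pytest.approx(
            res.stress, rel=1e-9)

    def test_rigid_motion_invariance(self, rng):
        dm = random_distance_matrix(rng, 8)
        res = nmds(dm, k=2, n_starts=5, seed=0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = res.coordinates.to_numpy() @ rot.T
        moved[:, 0] *= -1  # reflection
        assert kruskal_stress(dm, moved) == pytest.approx(res.stress, rel=1e-9)

    def test_coordinates_centred(self, rng):
        dm = random_distance_matrix(rng, 7)
        res = nmds(dm, k=2, n_starts=3, seed=0)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-10)

    def test_too_few_samples_is_error(self, rng):
        dm = random_distance_matrix(rng, 3)
        with pytest.raises(ValueError):
            nmds(dm, k=3)

    def test_all_equal_dissimilarities_warn(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(d, ids=list("abcd"))
        with pytest.warns(UserWarning, match="equal"):
            nmds(dm, k=2, n_starts=2, seed=0)
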