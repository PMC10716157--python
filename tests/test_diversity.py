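"""Alpha/beta diversity closed forms and age-trajectory behaviour."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from bifidoprof.diversity import (
    adjacent_age_dissimilarity,
    age_trend,
    alpha_diversity,
    beta_diversity,
    bray_curtis,
    faith_pd,
    jsd,
    shannon,
)


from tests_support_trees import brute_force_pd, random_tree  # noqa: E402


class TestAlpha:
    def test_shannon_uniform_is_log_k(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_single_zotu_sample(self):
        table = pd.DataFrame([[2000, 0]], index=["s"], columns=["a", "b"])
        out = alpha_diversity(table)
        assert out.loc["s", "observed"] == 1
        assert out.loc["s", "shannon"] == 0.0

    def test_shannon_maximal_at_uniform(self, rng):
        for _ in range(20):
            x = rng.integers(1, 100, size=6)
            assert shannon(x) <= np.log(6) + 1e-12

    def test_faith_pd_star_tree(self):
        tree = TreeNode.read(_io.StringIO("(A:1,B:1,C:1,D:1,E:1):0;"))
        assert faith_pd(tree, ["A", "C", "E"]) == pytest.approx(3.0)

    def test_faith_pd_matches_brute_force_on_random_trees(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 30))
            tree = random_tree(rng, n)
            tips = [t.name for t in tree.tips()]
            k = int(rng.integers(1, n + 1))
            obs = list(rng.choice(tips, size=k, replace=False))
            assert faith_pd(tree, obs) == pytest.approx(brute_force_pd(tree, set(obs)))

    def test_faith_pd_monotone_and_total(self, rng):
        tree = random_tree(rng, 12)
        tips = [t.name for t in tree.tips()]
        prev = 0.0
        for k in range(1, len(tips) + 1):
            cur = faith_pd(tree, tips[:k])
            assert cur >= prev - 1e-12
            prev = cur
        total = sum(n.length or 0.0 for n in tree.traverse() if n.parent is not None)
        assert faith_pd(tree, tips) == pytest.approx(total)

    def test_faith_pd_agrees_with_skbio(self, rng):
        from skbio.diversity.alpha import faith_pd as sk_faith

        tree = random_tree(rng, 10)
        tips = [t.name for t in tree.tips()]
        counts = (rng.random(10) < 0.5).astype(int)
        counts[0] = 1
        mine = faith_pd(tree, [t for t, c in zip(tips, counts) if c])
        assert mine == pytest.approx(float(sk_faith(counts, taxa=tips, tree=tree)))


class TestBeta:
    def test_identical_samples_zero(self):
        x = np.array([3.0, 1.0, 0.0])
        assert bray_curtis(x, x) == 0.0
        assert jsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports(self):
        x = np.array([1.0, 0.0])
        y = np.array([0.0, 2.0])
        assert bray_curtis(x, y) == pytest.approx(1.0)
        assert jsd(x, y) == pytest.approx(np.log(2))

    def test_elementwise_oracle(self, rng):
        for _ in range(20):
            x = rng.random(8)
            y = rng.random(8)
            assert bray_curtis(x, y) == pytest.approx(
                np.abs(x - y).sum() / (x + y).sum(), abs=1e-12)
            p, q = x / x.sum(), y / y.sum()
            m = (p + q) / 2

            def kl(a, b):
                mask = a > 0
                return float((a[mask] * np.log(a[mask] / b[mask])).sum())

            assert jsd(x, y) == pytest.approx(0.5 * kl(p, m) + 0.5 * kl(q, m), abs=1e-12)

    def test_matrix_properties(self, cohort):
        prof = cohort["profile"].iloc[:25]
        for metric, upper in (("bray_curtis", 1.0), ("jsd", np.log(2))):
            dm = beta_diversity(prof, metric)
            assert np.allclose(dm.data, dm.data.T)
            assert np.all(np.diag(dm.data) == 0)
            assert dm.data.min() >= 0 and dm.data.max() <= upper + 1e-12

    def test_zero_sum_sample_errors(self):
        table = pd.DataFrame([[0, 0], [1, 2]], index=["bad", "ok"], columns=["a", "b"])
        with pytest.raises(ValueError, match="bad"):
            beta_diversity(table, "bray_curtis")


class TestAgeTrajectory:
    def test_identical_neighbors_distance_zero(self):
        prof = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"])
        ages = pd.Series([5.3, 4.9], index=["a", "b"])
        points, _ = adjacent_age_dissimilarity(prof, ages)
        assert len(points) == 1
        assert points.iloc[0]["age_bin"] == 5
        assert points.iloc[0]["distance"] == 0.0

    def test_cross_pair_count(self, rng):
        m, n = 3, 4
        prof = pd.DataFrame(rng.random((m + n, 5)),
                            index=[f"s{i}" for i in range(m + n)])
        ages = pd.Series([4.2] * m + [5.7] * n, index=prof.index)
        points, _ = adjacent_age_dissimilarity(prof, ages)
        assert len(points) == m * n
        assert set(points["age_bin"]) == {5}

    def test_single_bin_yields_nothing(self, rng):
        prof = pd.DataFrame(rng.random((4, 3)), index=list("abcd"))
        ages = pd.Series([2.1, 2.5, 2.9, 2.0], index=prof.index)
        points, trend = adjacent_age_dissimilarity(prof, ages)
        assert points.empty and trend.empty

    def test_linear_feature_recovers_slope_one(self, rng):
        ages = pd.Series(np.linspace(0, 60, 80))
        res = age_trend(ages.copy(), ages)
        assert res["slope"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res["loess"], res["grid"], atol=0.5)
        assert res["annotations"][16.0] == pytest.approx(16.0, abs=0.5)

    def test_white_noise_slope_ci_covers_zero(self, rng):
        covered = 0
        for _ in range(40):
            ages = pd.Series(rng.uniform(0, 80, size=60))
            y = pd.Series(rng.normal(size=60), index=ages.index)
            res = age_trend(y, ages)
            if abs(res["slope"]) <= 1.96 * res["slope_se"]:
                covered += 1
        assert covered >= 0.9 * 40 - 3

    def test_breakpoint_shows_max_curvature_near_sixteen(self, rng):
        ages = pd.Series(np.linspace(0, 60, 300))
        y = pd.Series(np.where(ages <= 16, 2.0 * ages, 32.0), index=ages.index)
        y = y + rng.normal(scale=0.5, size=len(y))
        # a narrow span localizes the kink; wide spans smear curvature
        # toward the edges of the local window
        res = age_trend(y, ages, span=0.1)
        curv = np.abs(np.diff(res["loess"], 2))
        peak_age = res["grid"][1:-1][np.argmax(curv)]
        assert abs(peak_age - 16) <= 3

    def test_constant_feature_degenerates_gracefully(self):
        ages = pd.Series(np.linspace(0, 50, 30))
        y = pd.Series(np.ones(30), index=ages.index)
        res = age_trend(y, ages)
        assert res["slope"] == 0.0
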