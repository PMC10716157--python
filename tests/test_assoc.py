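"""The association battery: dbRDA, ridge, Mantel, LSD letters, Mann-Whitney,
geography correlations and BH control."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from scipy.spatial.distance import pdist, squareform

from bifidoprof.assoc import (
    anova_lsd_letters,
    bh_adjust,
    dbrda_stepwise,
    dbrda_univariate,
    design_matrix,
    genome_geo_correlation,
    haversine_km,
    linreg_adjusted,
    mann_whitney,
    mantel,
    mw_differential_counts,
    ridge_associate,
)


def bh_brute_force(p):
    """Independent oracle straight from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_and_equal(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.random(15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def direct_rda_r2(X_raw, covariate_design):
    """Oracle: RDA on the raw data matrix (constrained sum of squares
    fraction after column-centering both sides)."""
    Y = X_raw - X_raw.mean(axis=0)
    X = covariate_design - covariate_design.mean(axis=0)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    return (fitted**2).sum() / (Y**2).sum()


class TestDbrda:
    def test_perfectly_constrained_response(self, rng):
        n = 30
        cov = pd.Series(rng.normal(size=n), name="x")
        D = squareform(pdist(cov.to_numpy()[:, None]))
        res = dbrda_univariate(D, cov, n_perm=99, seed=1)
        assert res.estimate == pytest.approx(1.0, abs=1e-9)
        assert res.p == pytest.approx(1 / 100)

    def test_equals_direct_rda_on_euclidean_distances(self, rng):
        n, p = 40, 6
        raw = rng.normal(size=(n, p))
        cov = pd.Series(rng.normal(size=n), name="x")
        D = squareform(pdist(raw))
        res = dbrda_univariate(D, cov, n_perm=9, seed=2)
        r2_direct = direct_rda_r2(raw, cov.to_numpy()[:, None])
        # compare unadjusted R2 by undoing the Ezekiel adjustment (m=1)
        r2_dbrda = 1 - (1 - res.estimate) * (n - 2) / (n - 1)
        assert r2_dbrda == pytest.approx(r2_direct, abs=1e-8)

    def test_constant_covariate_rejected(self, rng):
        D = squareform(pdist(rng.normal(size=(12, 3))))
        with pytest.raises(ValueError):
            dbrda_univariate(D, pd.Series(np.ones(12), name="c"))

    def test_categorical_covariate_uses_dummy_block(self, rng):
        n = 36
        g = pd.Series(rng.choice(list("abc"), size=n), name="g")
        raw = rng.normal(size=(n, 4)) + (g == "a").to_numpy()[:, None] * 2.0
        D = squareform(pdist(raw))
        res = dbrda_univariate(D, g, n_perm=99, seed=3)
        assert res.p <= 0.05
        assert 0 < res.estimate < 1

    def test_null_adjusted_r2_near_zero(self, rng):
        vals = []
        for _ in range(30):
            raw = rng.normal(size=(40, 5))
            cov = pd.Series(rng.normal(size=40), name="x")
            res = dbrda_univariate(squareform(pdist(raw)), cov, n_perm=9, seed=4)
            vals.append(res.estimate)
        assert abs(np.mean(vals)) < 0.05


class TestStepwise:
    def test_planted_driver_selected_first(self, rng):
        # a weak secondary covariate keeps the global adjusted R2 above the
        # driver's marginal one, so the scope rule lets selection proceed
        n = 120
        driver = rng.normal(size=n)
        weak = rng.normal(size=n)
        raw = np.column_stack([driver * 1.5, weak * 0.5, rng.normal(size=(n, 3))])
        D = squareform(pdist(raw))
        cands = pd.DataFrame({"driver": driver, "weak": weak,
                              **{f"noise{j}": rng.normal(size=n) for j in range(4)}})
        sel = dbrda_stepwise(D, cands, n_perm=99, seed=5)
        assert len(sel) >= 1
        assert sel.iloc[0]["term"] == "driver"

    def test_duplicated_covariate_never_selected(self, rng):
        n = 100
        driver = rng.normal(size=n)
        weak = rng.normal(size=n)
        raw = np.column_stack([driver * 1.5, weak * 0.5, rng.normal(size=(n, 2))])
        D = squareform(pdist(raw))
        cands = pd.DataFrame({"driver": driver, "dup": driver.copy(),
                              "weak": weak, "noise": rng.normal(size=n)})
        sel = dbrda_stepwise(D, cands, n_perm=99, seed=6)
        picked = list(sel["term"])
        assert ("driver" in picked) != ("dup" in picked)  # only one of the pair

    def test_all_noise_rarely_selects(self, rng):
        n = 50
        hits = 0
        for _ in range(10):
            D = squareform(pdist(rng.normal(size=(n, 4))))
            cands = pd.DataFrame({f"x{j}": rng.normal(size=n) for j in range(4)})
            sel = dbrda_stepwise(D, cands, n_perm=99, seed=int(rng.integers(1 << 30)))
            hits += len(sel) > 1
        assert hits <= 3


class TestRidge:
    def test_zero_penalty_equals_ols(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = pd.Series(X["a"] * 0.7 - X["b"] * 0.2 + rng.normal(size=n))
        res = ridge_associate(y, X, lam=0.0)
        Xz = (X - X.mean()) / X.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        beta = np.linalg.lstsq(np.column_stack([np.ones(n), Xz]), yz, rcond=None)[0][1:]
        np.testing.assert_allclose([r.estimate for r in res], beta, atol=1e-8)

    def test_infinite_penalty_shrinks_to_zero(self, rng):
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=list("ab"))
        y = pd.Series(X["a"] + rng.normal(size=n))
        res = ridge_associate(y, X, lam=1e12)
        assert all(abs(r.estimate) < 1e-6 for r in res)

    def test_negative_penalty_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=list("ab"))
        with pytest.raises(ValueError):
            ridge_associate(pd.Series(rng.normal(size=20)), X, lam=-1.0)

    def test_sign_and_ordering_recovery(self, rng):
        ok = 0
        for _ in range(20):
            n = 150
            lat = rng.normal(size=n)
            age = rng.normal(size=n)
            y = pd.Series(0.5 * lat - 0.5 * age + rng.normal(size=n))
            X = pd.DataFrame({"latitude": lat, "age": age,
                              "noise": rng.normal(size=n)})
            res = {r.term: r.estimate for r in ridge_associate(y, X)}
            ok += (res["latitude"] > 0 > res["age"]
                   and abs(res["noise"]) < min(res["latitude"], -res["age"]))
        assert ok >= 18

    def test_reference_level_excluded_from_dummies(self):
        X = pd.DataFrame({"sex": ["female", "male", "male", "female"]})
        mat, names = design_matrix(X)
        assert names == ["sex[male]"]
        np.testing.assert_allclose(mat[:, 0], [0, 1, 1, 0])


class TestMantel:
    def test_self_correlation(self, rng):
        A = squareform(pdist(rng.normal(size=(15, 3))))
        r, p = mantel(A, A, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_monotone_transform_positive(self, rng):
        A = squareform(pdist(rng.normal(size=(15, 3))))
        r, _ = mantel(A, np.sqrt(A), n_perm=99, seed=1)
        assert r > 0.9

    def test_agrees_with_skbio(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as sk_mantel

        A = squareform(pdist(rng.normal(size=(12, 3))))
        B = squareform(pdist(rng.normal(size=(12, 3))))
        r, _ = mantel(A, B, n_perm=99, seed=2)
        sk_r, _, _ = sk_mantel(DistanceMatrix(A), DistanceMatrix(B), permutations=0)
        assert r == pytest.approx(float(sk_r), abs=1e-12)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mantel(np.zeros((3, 3)), np.zeros((4, 4)))


class TestLinregAdjusted:
    def _frame(self, rng, n=80):
        return pd.DataFrame({
            "age": rng.uniform(0, 80, size=n),
            "sex": rng.choice(["female", "male"], size=n),
        })

    def test_exact_relationship(self, rng):
        adj = self._frame(rng)
        target = pd.Series(rng.normal(size=80), name="lat")
        res = linreg_adjusted(target.copy(), target, adj)
        assert res.estimate == pytest.approx(1.0, abs=1e-6)
        assert res.p < 1e-10

    def test_permutation_destroys_planted_effect(self, rng):
        adj = self._frame(rng)
        target = pd.Series(rng.normal(size=80), name="lat")
        y = pd.Series(0.8 * target + rng.normal(scale=0.5, size=80))
        assert linreg_adjusted(y, target, adj).p < 1e-6
        shuffled = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        assert linreg_adjusted(shuffled, target, adj).p > 0.01

    def test_collinear_design_rejected(self, rng):
        adj = self._frame(rng)
        target = pd.Series(adj["age"].to_numpy(), name="age_copy")
        with pytest.raises(ValueError, match="rank"):
            linreg_adjusted(pd.Series(rng.normal(size=80)), target, adj)


class TestAnovaLsd:
    def test_single_group_letter_a(self, rng):
        y = pd.Series(rng.normal(size=10))
        g = pd.Series(["only"] * 10)
        out = anova_lsd_letters(y, g)
        assert out["letters"] == {"only": "a"}

    def test_separated_groups_get_distinct_letters(self, rng):
        y = pd.Series(np.r_[rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        g = pd.Series(["low"] * 20 + ["high"] * 20)
        out = anova_lsd_letters(y, g)
        assert set(out["letters"]["low"]).isdisjoint(out["letters"]["high"])
        assert out["p"] < 1e-10

    def test_homogeneous_groups_share_a_letter(self, rng):
        share = 0
        for _ in range(20):
            y = pd.Series(rng.normal(size=45))
            g = pd.Series(rng.choice(list("abc"), size=45))
            letters = anova_lsd_letters(y, g)["letters"]
            common = set.intersection(*(set(v) for v in letters.values()))
            share += bool(common)
        assert share >= 16

    def test_tiny_group_dropped(self, rng):
        y = pd.Series(np.r_[rng.normal(size=10), [5.0]])
        g = pd.Series(["a"] * 10 + ["singleton"])
        out = anova_lsd_letters(y, g)
        assert "singleton" not in out["letters"]


def mw_permutation_oracle(a, b):
    """Enumerate every permutation of the pooled values (independent of
    the combination-based implementation)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    mu = n1 * len(b) / 2.0

    def u_stat(vals):
        ranks = st.rankdata(vals)
        return ranks[:n1].sum() - n1 * (n1 + 1) / 2

    obs = abs(u_stat(pooled) - mu)
    hits = total = 0
    seen = set()
    for perm in itertools.permutations(pooled):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if abs(u_stat(list(perm)) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_constant_data_p_one(self):
        _, p = mann_whitney([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_exact_matches_permutation_enumeration(self):
        a, b = [5.0, 6.0, 7.0, 8.0], [0.0, 0.0, 1.0, 1.0]
        u, p = mann_whitney(a, b)
        assert u == 16.0
        assert p == pytest.approx(mw_permutation_oracle(a, b))

    def test_exact_with_ties_matches_oracle(self, rng):
        for _ in range(5):
            a = list(rng.integers(0, 4, size=4).astype(float))
            b = list(rng.integers(0, 4, size=3).astype(float))
            if np.ptp(a + b) == 0:
                continue
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(mw_permutation_oracle(a, b))

    def test_large_n_close_to_scipy(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.8, size=25)
        _, p = mann_whitney(a, b)
        ref = st.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(float(ref), rel=1e-6)

    def test_differential_counts_recovers_planted_families(self, rng):
        n_fam, n_planted = 40, 4
        a = pd.DataFrame(rng.poisson(3, size=(12, n_fam)),
                         columns=[f"f{i}" for i in range(n_fam)])
        b = a.copy() + 0
        b = pd.DataFrame(rng.poisson(3, size=(12, n_fam)), columns=a.columns)
        for i in range(n_planted):
            b[f"f{i}"] += 8
        out = mw_differential_counts(a, b).set_index("family")
        flagged = set(out.index[out.p_adj < 0.05])
        assert {f"f{i}" for i in range(n_planted)} <= flagged
        false = flagged - {f"f{i}" for i in range(n_planted)}
        assert len(false) <= max(1, int(0.1 * len(flagged)))
        assert (out.loc[list(flagged), "direction"] == -1).all()


class TestGeoCorrelation:
    def test_proportional_distances_give_r_one(self, rng):
        sites = pd.DataFrame({"lat": [20.0, 25.0, 30.0, 40.0],
                              "lon": [100.0, 100.0, 100.0, 100.0]},
                             index=list("abcd"))
        n = len(sites)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                D[i, j] = haversine_km(sites.iloc[i].lat, 100, sites.iloc[j].lat, 100) * 1e-5
        from skbio import DistanceMatrix

        out = genome_geo_correlation(DistanceMatrix(D, ids=list(sites.index)), sites)
        assert out["r_geo"] == pytest.approx(1.0)
        assert out["r_lat"] == pytest.approx(1.0)
        assert np.isnan(out["r_lon"])  # no longitudinal spread

    def test_single_site_is_nan(self):
        sites = pd.DataFrame({"lat": [30.0] * 3, "lon": [110.0] * 3}, index=list("abc"))
        D = np.array([[0, 0.1, 0.2], [0.1, 0, 0.1], [0.2, 0.1, 0]])
        from skbio import DistanceMatrix

        out = genome_geo_correlation(DistanceMatrix(D, ids=list("abc")), sites)
        assert np.isnan(out["r_geo"])

    def test_missing_coordinates_excluded(self, rng):
        sites = pd.DataFrame({"lat": [20.0, np.nan, 30.0], "lon": [100.0, 105.0, 110.0]},
                             index=list("abc"))
        from skbio import DistanceMatrix

        D = squareform(pdist(rng.normal(size=(3, 2))))
        out = genome_geo_correlation(DistanceMatrix(D, ids=list("abc")), sites)
        assert out["n_excluded"] == 2 and out["n_pairs"] == 1
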