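"""PCA, MANOVA, Welch/Games-Howell, bootstrap and correlation clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epidiverge import population_stats as ps

from conftest import make_matrix


def cohort_matrix(rng, n_sites=300, shift_frac=0.0, n_per_group=3, shift=0.4):
    """Two-population matrix; a fraction of sites differs between groups."""
    pos = np.arange(n_sites) * 100 + 50
    base = rng.uniform(0.2, 0.8, size=n_sites)
    shifted = base.copy()
    k = int(shift_frac * n_sites)
    shifted[:k] = np.clip(shifted[:k] + shift, 0.01, 0.99)
    pops, meth, tot = {}, [], []
    for g, p in (("A", base), ("B", shifted)):
        for i in range(n_per_group):
            s = f"{g}{i}"
            pops[s] = g
            t = np.full(n_sites, 40)
            meth.append(rng.binomial(t, p))
            tot.append(t)
    return make_matrix(pos, np.column_stack(meth), np.column_stack(tot), pops)


class TestPCA:
    def test_planted_clusters_separate_on_pc1(self, rng):
        m = cohort_matrix(rng, shift_frac=0.2)
        res = ps.pca_methylome(m)
        pc1 = res.scores["PC1"].to_numpy()
        a, b = pc1[:3], pc1[3:]
        gap = abs(a.mean() - b.mean())
        spread = max(a.std(ddof=1), b.std(ddof=1), 1e-9)
        assert gap > 3 * spread
        # silhouette-style check: within-group distances << between
        from itertools import product
        within = [abs(x - y) for g in (a, b) for x, y in product(g, g) if x != y]
        between = [abs(x - y) for x, y in product(a, b)]
        assert np.mean(within) < np.mean(between) / 2

    def test_variance_explained_matches_eigendecomposition(self, rng):
        m = cohort_matrix(rng)
        res = ps.pca_methylome(m)
        lv = m.levels().T
        sd = lv.std(axis=0, ddof=1)
        z = (lv[:, sd > 0] - lv[:, sd > 0].mean(axis=0)) / sd[sd > 0]
        ev = np.linalg.eigvalsh(np.cov(z.T))[::-1]
        want = ev[: len(res.variance_explained)] / ev.sum()
        assert np.allclose(res.variance_explained, want, atol=1e-8)
        assert res.variance_explained.sum() <= 1 + 1e-9

    def test_scores_centred(self, rng):
        res = ps.pca_methylome(cohort_matrix(rng))
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-9)

    def test_identical_samples_error(self):
        m = make_matrix([10, 20], [[3, 3], [4, 4]], [[10, 10], [10, 10]],
                        {"a": "A", "b": "A"})
        with pytest.raises(ValueError, match="zero variance"):
            ps.pca_methylome(m)


class TestManova:
    def scores(self, rng, sep=0.0, n=12):
        labels = np.repeat(["a", "b", "c"], n)
        y = rng.normal(size=(3 * n, 2))
        y[labels == "c", 0] += sep
        return pd.DataFrame(y, columns=["PC1", "PC2"]), labels

    def test_df1_matches_three_groups_two_components(self, rng):
        sc, labels = self.scores(rng)
        F, df1, df2, p = ps.manova_pc_scores(sc, labels)
        assert df1 == 4

    def test_separated_groups_tiny_p(self, rng):
        sc, labels = self.scores(rng, sep=8.0)
        F, df1, df2, p = ps.manova_pc_scores(sc, labels)
        assert p < 1e-6

    def test_null_p_roughly_uniform(self):
        ps_ = [ps.manova_pc_scores(*self.scores(np.random.default_rng(s)))[3]
               for s in range(40)]
        assert 0.2 < np.mean(ps_) < 0.8
        assert (np.array(ps_) < 0.05).mean() < 0.25

    def test_matches_statsmodels_pillai(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        sc, labels = self.scores(rng, sep=1.0)
        F, df1, df2, p = ps.manova_pc_scores(sc, labels)
        df = sc.copy()
        df["grp"] = labels
        mv = MANOVA.from_formula("PC1 + PC2 ~ grp", data=df)
        tab = mv.mv_test().results["grp"]["stat"]
        row = tab.loc["Pillai's trace"]
        assert F == pytest.approx(float(row["F Value"]), rel=1e-8)
        assert p == pytest.approx(float(row["Pr > F"]), rel=1e-6, abs=1e-12)

    def test_group_smaller_than_components_error(self, rng):
        sc = pd.DataFrame(rng.normal(size=(4, 2)), columns=["PC1", "PC2"])
        with pytest.raises(ValueError, match="fewer samples"):
            ps.manova_pc_scores(sc, ["a", "a", "a", "b"])


class TestWelchGamesHowell:
    def test_equal_groups_f_zero_p_one(self):
        out = ps.welch_games_howell([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                                    ["a"] * 3 + ["b"] * 3)
        assert out["welch_F"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_two_groups_reduces_to_welch_t(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 2, 12)
        F, df1, df2, p = ps.welch_anova(np.concatenate([x, y]),
                                        ["a"] * 8 + ["b"] * 12)
        t, p_t = stats.ttest_ind(x, y, equal_var=False)
        assert F == pytest.approx(t**2, abs=1e-10)
        assert p == pytest.approx(p_t, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(0.5, 2, 12),
                               rng.normal(3, 1, 11)])
        labels = ["a"] * 10 + ["b"] * 12 + ["c"] * 11
        F, df1, df2, p = ps.welch_anova(vals, labels)
        df = pd.DataFrame({"v": vals, "g": labels})
        want = pg.welch_anova(data=df, dv="v", between="g")
        assert F == pytest.approx(float(want["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(want["p_unc"].iloc[0]), rel=1e-6)
        gh = ps.games_howell(vals, labels)
        want_gh = pg.pairwise_gameshowell(data=df, dv="v", between="g")
        got = gh.set_index(["group1", "group2"])["p_adj"]
        for r in want_gh.itertuples():
            key = (r.A, r.B) if (r.A, r.B) in got.index else (r.B, r.A)
            assert got[key] == pytest.approx(float(r.pval), abs=1e-6)

    def test_shifted_group_all_pairs_significant(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(0, 1, 12),
                               rng.normal(3, 1, 12)])
        labels = ["a"] * 12 + ["b"] * 12 + ["c"] * 12
        gh = ps.games_howell(vals, labels)
        third = gh[(gh["group1"] == "c") | (gh["group2"] == "c")]
        assert (third["p_adj"] < 0.008).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ps.welch_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestBootstrap:
    def test_identical_constant_samples(self):
        d, (lo, hi) = ps.bootstrap_mean_diff([5.0] * 8, [5.0] * 8, n_boot=100)
        assert d == 0 and lo == hi == 0

    def test_constant_shift_exact(self):
        d, (lo, hi) = ps.bootstrap_mean_diff([7.0] * 5, [4.0] * 5, n_boot=100)
        assert d == 3.0 and (lo, hi) == (3.0, 3.0)

    def test_coverage_on_normal_simulations(self):
        cover = 0
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            a = rng.normal(1.0, 1.0, 80)
            b = rng.normal(0.0, 1.0, 80)
            _, (lo, hi) = ps.bootstrap_mean_diff(a, b, n_boot=400, seed=seed)
            cover += lo <= 1.0 <= hi
        assert cover >= 48  # ~95% nominal; generous floor at small n_rep

    def test_deterministic_per_seed(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        r1 = ps.bootstrap_mean_diff(a, b, n_boot=200, seed=5)
        r2 = ps.bootstrap_mean_diff(a, b, n_boot=200, seed=5)
        assert r1 == r2


def brute_force_complete_linkage(dist):
    """Exhaustive agglomeration with complete linkage on a condensed matrix."""
    from scipy.spatial.distance import squareform

    d = squareform(dist)
    clusters = {i: [i] for i in range(len(d))}
    heights = []
    nxt = len(d)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        nxt += 1
    return heights


class TestCorrelationCluster:
    def test_identical_samples_merge_at_zero(self, rng):
        x = rng.normal(size=50)
        data = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        out = ps.correlation_cluster(data)
        assert out["linkage"][0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_two_planted_groups_cut_cleanly(self, rng):
        base1 = rng.normal(size=80)
        base2 = rng.normal(size=80)
        cols = {f"a{i}": base1 + rng.normal(0, 0.2, 80) for i in range(3)}
        cols.update({f"b{i}": base2 + rng.normal(0, 0.2, 80) for i in range(3)})
        out = ps.correlation_cluster(pd.DataFrame(cols))
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(out["linkage"], 2, criterion="maxclust")
        names = list(pd.DataFrame(cols).columns)
        ga = {two[i] for i, n in enumerate(names) if n.startswith("a")}
        gb = {two[i] for i, n in enumerate(names) if n.startswith("b")}
        assert len(ga) == 1 and len(gb) == 1 and ga != gb

    def test_linkage_heights_match_bruteforce(self, rng):
        data = pd.DataFrame(rng.normal(size=(40, 6)),
                            columns=list("abcdef"))
        out = ps.correlation_cluster(data)
        from scipy.spatial.distance import pdist

        dist = pdist(out["correlation"].to_numpy())
        want = brute_force_complete_linkage(dist)
        assert np.allclose(sorted(out["linkage"][:, 2]), sorted(want))

    def test_monotone_transform_invariance(self, rng):
        data = pd.DataFrame(rng.uniform(1, 2, size=(50, 4)),
                            columns=list("abcd"))
        a = ps.correlation_cluster(data)
        b = ps.correlation_cluster(np.exp(data))
        assert np.allclose(a["linkage"][:, 2], b["linkage"][:, 2])

    def test_constant_sample_error(self, rng):
        data = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(ValueError, match="b"):
            ps.correlation_cluster(data)

    def test_newick_has_all_leaves(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
        out = ps.correlation_cluster(data)
        for leaf in "wxyz":
            assert leaf in out["newick"]


class TestCrossPlatform:
    def test_single_covered_site_value(self):
        m = make_matrix([100], [[9]], [[10]], {"s1": "A"})
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 50, "end": 150}])
        out = ps.cross_platform_matrix(m, dmrs)
        assert out.iloc[0, 0] == pytest.approx(0.9)

    def test_uncovered_dmr_missing(self):
        m = make_matrix([100], [[9]], [[10]], {"s1": "A"})
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 500, "end": 600}])
        out = ps.cross_platform_matrix(m, dmrs)
        assert np.isnan(out.iloc[0, 0])

    def test_subsampled_sites_cluster_like_full(self, rng):
        m = cohort_matrix(rng, n_sites=600, shift_frac=0.3)
        dmrs = pd.DataFrame(
            [{"chrom": "chr1", "start": k * 3000, "end": k * 3000 + 3000}
             for k in range(20)]
        )
        # subsample 10% of sites (RRBS-like)
        keep = np.zeros(m.n_sites, dtype=bool)
        keep[rng.choice(m.n_sites, size=60, replace=False)] = True
        sub = m.subset_sites(keep)
        full = ps.cross_platform_matrix(m, dmrs)
        red = ps.cross_platform_matrix(sub, dmrs)
        usable = red.columns[red.notna().all(axis=0)]
        out = ps.correlation_cluster(red[usable].T)
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(out["linkage"], 2, criterion="maxclust")
        labels = [s[0] for s in red.index]
        ga = {two[i] for i, l in enumerate(labels) if l == "A"}
        gb = {two[i] for i, l in enumerate(labels) if l == "B"}
        assert ga != gb and len(ga) == 1 and len(gb) == 1
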