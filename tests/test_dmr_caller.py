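"""DMR caller: smoothing, Wald tests, region formation, filters, merging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epidiverge.config import ConfigError, SimulationConfig
from epidiverge import dmr_caller as dc
from epidiverge import methylome_io as mio
from epidiverge import synthetic_data as sd

from conftest import make_matrix


class TestSmoothLevels:
    def test_isolated_site_keeps_its_level(self):
        m = make_matrix([1000], [[6]], [[10]], {"s1": "popA"})
        out = dc.smooth_levels(m, "popA", bandwidth=500)
        assert out[0] == pytest.approx(0.6)

    def test_constant_region_preserved(self):
        pos = np.arange(0, 500, 25)
        total = np.full((len(pos), 2), 10)
        meth = np.full((len(pos), 2), 3)
        m = make_matrix(pos, meth, total, {"s1": "popA", "s2": "popA"})
        out = dc.smooth_levels(m, "popA", bandwidth=500)
        assert np.allclose(out, 0.3)

    def test_matches_bruteforce_weighted_average(self, rng):
        pos = np.sort(rng.choice(2000, size=20, replace=False))
        total = rng.integers(1, 40, size=(20, 2))
        meth = rng.binomial(total, 0.5)
        m = make_matrix(pos, meth, total, {"a": "popA", "b": "popA"})
        out = dc.smooth_levels(m, "popA", bandwidth=500)
        pooled_m = meth.sum(axis=1)
        pooled_n = total.sum(axis=1)
        for i, p in enumerate(pos):
            w = np.abs(pos - p) <= 250
            assert out[i] == pytest.approx(pooled_m[w].sum() / pooled_n[w].sum())

    def test_step_profile_is_monotone(self):
        pos = np.arange(0, 2000, 100)
        meth = np.where(pos < 1000, 0, 20)[:, None]
        total = np.full((len(pos), 1), 20)
        m = make_matrix(pos, meth, total, {"s1": "popA"})
        out = dc.smooth_levels(m, "popA", bandwidth=500)
        assert np.all(np.diff(out) >= -1e-12)

    def test_bad_bandwidth(self):
        m = make_matrix([1], [[1]], [[2]], {"s1": "popA"})
        with pytest.raises(ConfigError):
            dc.smooth_levels(m, "popA", bandwidth=0)


class TestWaldTest:
    def test_identical_groups_null_identity(self):
        diff, stat, p = dc.wald_test([5, 6], [10, 10], [5, 6], [10, 10])
        assert diff == 0 and stat == 0 and p == 1.0

    def test_extreme_counts_variance_floor(self):
        # all-zero vs all-full counts: clipped p keeps the SE finite
        diff, stat, p = dc.wald_test([0, 0], [30, 30], [30, 30], [30, 30])
        assert diff == -1.0 and np.isfinite(stat) and p < 1e-10

    def test_type_one_error_calibrated(self):
        # simulated null over many sites: rejection rate approx alpha
        c = SimulationConfig(seed=41, n_chromosomes=1, chrom_length=1_000_000,
                             n_genes=60, n_orphan_cgis=12, n_planted_dmrs=0,
                             n_planted_degs=0)
        g = sd.generate_genome(c)
        m, _ = sd.simulate_methylation_cohort(g, c)
        res = dc.test_sites(mio.filter_coverage(m), "benthic", "littoral")
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.03 < frac < 0.07

    def test_power_at_planted_difference(self):
        # 45% planted difference, coverage ~30, 3 vs 3: most DMR sites significant
        c = SimulationConfig(seed=42, n_chromosomes=1, chrom_length=1_000_000,
                             n_genes=60, n_orphan_cgis=12, n_planted_dmrs=20,
                             dmr_sites_range=(10, 232), n_planted_degs=0)
        g = sd.generate_genome(c)
        m, truth = sd.simulate_methylation_cohort(g, c)
        res = dc.test_sites(mio.filter_coverage(m), "benthic", "littoral")
        res = res.set_index("pos")
        hit = tot = 0
        for r in truth.dmrs.itertuples():
            sel = res[(res.index >= r.start) & (res.index < r.end)]
            hit += int((sel["p_value"] < 0.05).sum())
            tot += len(sel)
        assert hit / tot >= 0.9

    def test_vectorised_matches_single_site_reference(self, rng):
        pos = np.sort(rng.choice(10_000, size=30, replace=False))
        total = rng.integers(5, 60, size=(30, 6))
        meth = rng.binomial(total, 0.4)
        pops = {f"s{i}": ("popA" if i < 3 else "popB") for i in range(6)}
        m = make_matrix(pos, meth, total, pops)
        res = dc.test_sites(m, "popA", "popB", bandwidth=1.0)  # no neighbours
        for i in range(30):
            diff, stat, p = dc.wald_test(
                meth[i, :3], total[i, :3], meth[i, 3:], total[i, 3:],
            )
            # bandwidth 1 -> window is the site itself; dispersion pooling
            # differs, so compare the difference and the level estimates only
            assert res["diff"].iloc[i] == pytest.approx(diff, abs=1e-12)


def brute_force_candidates(pos, sig, max_gap, min_frac):
    """All containment-maximal windows satisfying the run rules, coalesced."""
    n = len(pos)
    wins = []
    for i in range(n):
        for j in range(i, n):
            if not (sig[i] and sig[j]):
                continue
            gaps_ok = all(pos[k + 1] - pos[k] <= max_gap for k in range(i, j))
            frac_ok = np.mean(sig[i:j + 1]) >= min_frac - 1e-12
            if gaps_ok and frac_ok:
                wins.append((i, j))
    maximal = [w for w in wins
               if not any(o != w and o[0] <= w[0] and o[1] >= w[1] for o in wins)]
    maximal.sort()
    merged = []
    for u, v in maximal:
        if merged and u <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], v)
        else:
            merged.append([u, v])
    return [(pos[u], pos[v] + 1) for u, v in merged]


class TestCallCandidateRegions:
    def results_frame(self, pos, sig, diff=0.5):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": pos,
                "raw_a": 0.8,
                "raw_b": 0.3,
                "diff": np.where(sig, diff, 0.0),
                "p_value": np.where(sig, 0.001, 0.5),
            }
        )

    def test_no_significant_sites_empty(self):
        res = self.results_frame(np.arange(0, 100, 10), np.zeros(10, bool))
        assert len(dc.call_candidate_regions(res)) == 0

    def test_single_run_boundaries(self):
        pos = np.array([0, 16, 32, 48, 64, 80])
        res = self.results_frame(pos, np.ones(6, bool))
        out = dc.call_candidate_regions(res)
        assert len(out) == 1
        assert out.iloc[0][["start", "end", "n_cpg"]].tolist() == [0, 81, 6]

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(st.booleans(), min_size=1, max_size=20),
        st.lists(st.integers(1, 150), min_size=20, max_size=20),
        st.sampled_from([0.3, 0.5, 0.7]),
    )
    def test_matches_exhaustive_enumeration(self, sig, gaps, min_frac):
        sig = np.array(sig, dtype=bool)
        pos = np.cumsum(gaps[: len(sig)])
        res = self.results_frame(pos, sig)
        out = dc.call_candidate_regions(
            res, max_gap=100, min_sig_fraction=min_frac, min_abs_diff=0.1
        )
        want = brute_force_candidates(pos, sig, 100, min_frac)
        got = list(zip(out["start"], out["end"]))
        assert got == want


class TestFilterDmrs:
    def candidate(self, n_cpg, diff, length):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "end": 100 + length,
              "n_cpg": n_cpg, "n_sig": n_cpg, "mean_a": 0.5 + diff / 2,
              "mean_b": 0.5 - diff / 2, "mean_diff": diff}]
        )

    @pytest.mark.parametrize("n_cpg,diff,length,kept", [
        (3, 0.60, 120, False),   # too few CpGs
        (15, 0.24, 250, False),  # difference below 25%
        (4, 0.45, 50, True),     # boundary of all three filters
        (4, 0.25, 50, True),
        (10, 0.30, 49, False),   # too short
        (10, -0.30, 200, True),  # loss direction counts by magnitude
    ])
    def test_filter_cascade(self, n_cpg, diff, length, kept):
        out = dc.filter_dmrs(self.candidate(n_cpg, diff, length))
        assert (len(out) == 1) == kept
        if kept:
            assert out["direction"].iloc[0] == ("gain" if diff > 0 else "loss")

    def test_every_emitted_dmr_satisfies_all_filters(self, small_filtered):
        dmrs = dc.call_dmrs(small_filtered, "benthic", "littoral")
        assert (dmrs["n_cpg"] >= 4).all()
        assert (np.abs(dmrs["mean_diff"]) >= 0.25).all()
        assert ((dmrs["end"] - dmrs["start"]) >= 50).all()

    def test_group_swap_flips_directions_same_intervals(self, small_filtered):
        a = dc.call_dmrs(small_filtered, "benthic", "littoral")
        b = dc.call_dmrs(small_filtered, "littoral", "benthic")
        pd.testing.assert_frame_equal(
            a[["chrom", "start", "end", "n_cpg"]],
            b[["chrom", "start", "end", "n_cpg"]],
        )
        assert np.allclose(a["mean_diff"], -b["mean_diff"])
        assert (
            a["direction"].map({"gain": "loss", "loss": "gain"}) == b["direction"]
        ).all()


class TestMergeDmrSets:
    def mk(self, rows, comparison="x_vs_y"):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": s, "end": e, "n_cpg": 5,
              "mean_a": 0.6, "mean_b": 0.2, "mean_diff": 0.4,
              "direction": "gain", "comparison": comparison}
             for s, e in rows]
        )

    def test_disjoint_sets_concatenate(self):
        out = dc.merge_dmr_sets([self.mk([(0, 10)]), self.mk([(50, 60)], "y_vs_z")])
        assert len(out) == 2

    def test_overlap_coalesces_with_both_provenances(self):
        out = dc.merge_dmr_sets([self.mk([(100, 200)]), self.mk([(150, 300)], "y_vs_z")])
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["start"], r["end"]) == (100, 300)
        assert r["comparisons"] == ("x_vs_y", "y_vs_z")

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 180), st.integers(1, 40)),
                    min_size=1, max_size=15))
    def test_matches_occupancy_scan(self, raw):
        rows = [(s, min(s + l, 200)) for s, l in raw]
        out = dc.merge_dmr_sets([self.mk(rows)])
        occ = np.zeros(201, dtype=bool)
        for s, e in rows:
            occ[s:e] = True
        got = np.zeros(201, dtype=bool)
        for r in out.itertuples():
            got[r.start:r.end] = True
        assert np.array_equal(got, occ)
        # bookended/overlapping intervals coalesced: gaps between merged rows
        starts = out["start"].to_numpy()
        ends = out["end"].to_numpy()
        assert np.all(starts[1:] > ends[:-1])


class TestSummarize:
    def test_single_dmr(self):
        d = pd.DataFrame([{"chrom": "c", "start": 0, "end": 250, "n_cpg": 15,
                           "mean_a": 0.8, "mean_b": 0.3, "mean_diff": 0.5,
                           "direction": "gain"}])
        s = dc.summarize_dmrs(d)
        assert s["length_median"] == 250 and s["n"] == 1

    def test_three_lengths_median_and_range(self):
        rows = [{"chrom": "c", "start": 0, "end": l, "n_cpg": 10,
                 "mean_a": .7, "mean_b": .2, "mean_diff": .5, "direction": "gain"}
                for l in (50, 250, 3000)]
        s = dc.summarize_dmrs(pd.DataFrame(rows))
        assert s["length_range"] == (50, 3000)
        assert s["length_median"] == 250

    def test_matches_direct_recomputation(self, rng):
        lengths = rng.integers(50, 3000, size=30)
        rows = [{"chrom": "c", "start": 0, "end": int(l), "n_cpg": int(n),
                 "mean_a": .7, "mean_b": .2, "mean_diff": d, "direction": dr}
                for l, n, d, dr in zip(
                    lengths, rng.integers(4, 232, size=30),
                    rng.uniform(-0.8, 0.8, size=30),
                    rng.choice(["gain", "loss"], size=30))]
        df = pd.DataFrame(rows)
        df["direction"] = np.where(df["mean_diff"] > 0, "gain", "loss")
        s = dc.summarize_dmrs(df)
        assert s["length_median"] == np.median(lengths)
        assert s["gain_fraction"] == pytest.approx((df["mean_diff"] > 0).mean())

    def test_empty_returns_zeros(self):
        assert dc.summarize_dmrs(pd.DataFrame(columns=["end"]))["n"] == 0
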