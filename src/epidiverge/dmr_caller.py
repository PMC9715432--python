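"""Differentially methylated region (DMR) calling between two populations.

Per-site inference follows the smoothed beta-binomial Wald-test design:

* group methylation levels are smoothed with a coverage-weighted boxcar
  kernel (default span 500 bp) by pooling methylated/total counts over all
  sites within +/- span/2 of the focal site;
* the Wald statistic is the smoothed group difference divided by a standard
  error from beta-binomial variance, with a method-of-moments dispersion
  estimated per group from the window-aggregated per-sample counts, smoothed
  along the chromosome and floored at 1e-3;
* two-sided p-values come from the standard normal.

Candidate regions are maximal runs of significant sites (p below threshold
and |smoothed difference| above a floor), allowing interspersed
non-significant sites while the significant fraction stays above a minimum
and consecutive sites are no further apart than a maximum gap.  Emitted DMRs
must then pass the region filters: >= 25% average raw methylation
difference, >= 4 CpG sites and >= 50 bp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError
from .methylome_io import MethylomeMatrix, group_complete_mask

PHI_FLOOR = 1e-3
P_CLIP = 1e-3


# ---------------------------------------------------------------------------
# Single-site Wald test (reference implementation; also used at region level)


def wald_test(meth_a, total_a, meth_b, total_b,
              smoothed_a: float | None = None, smoothed_b: float | None = None,
              phi_floor: float = PHI_FLOOR) -> tuple[float, float, float]:
    """Beta-binomial Wald test at one site (or one aggregated region).

    ``meth_*``/``total_*`` are per-sample counts.  Returns
    ``(difference, statistic, p_value)`` where difference is the (smoothed,
    if given, else pooled) group A minus group B level.
    """
    ma, na = np.asarray(meth_a, float), np.asarray(total_a, float)
    mb, nb = np.asarray(meth_b, float), np.asarray(total_b, float)
    ma, na = ma[na > 0], na[na > 0]
    mb, nb = mb[nb > 0], nb[nb > 0]
    if na.size == 0 or nb.size == 0:
        raise ValueError("each group needs >= 1 sample with coverage")
    pa = smoothed_a if smoothed_a is not None else ma.sum() / na.sum()
    pb = smoothed_b if smoothed_b is not None else mb.sum() / nb.sum()
    diff = pa - pb
    var = 0.0
    for m, n, p in ((ma, na, pa), (mb, nb, pb)):
        phi = max(_mom_phi(m, n, p), phi_floor)
        pc = min(max(p, P_CLIP), 1 - P_CLIP)
        var += np.sum(n * pc * (1 - pc) * (1 + (n - 1) * phi)) / n.sum() ** 2
    stat = diff / np.sqrt(var)
    p_value = 1.0 if diff == 0 else 2.0 * stats.norm.sf(abs(stat))
    return float(diff), float(stat), float(min(p_value, 1.0))


def _mom_phi(m: np.ndarray, n: np.ndarray, p: float) -> float:
    """Method-of-moments beta-binomial intra-class correlation for one group."""
    if m.size < 2:
        return 0.0
    pv = min(max(p, P_CLIP), 1 - P_CLIP)
    pv = pv * (1 - pv)
    q = m / n
    s2 = float(np.var(q, ddof=1))
    h = float(np.mean(1.0 / n))
    if h >= 1.0:
        return 0.0
    return (s2 / pv - h) / (1.0 - h)


# ---------------------------------------------------------------------------
# Vectorised per-site testing with smoothing


def _pooled_mom_phi(meth: np.ndarray, total: np.ndarray,
                    pooled_p: np.ndarray) -> float:
    """Chromosome-pooled method-of-moments dispersion for one group.

    Per-site MoM estimates (between-sample variance of raw proportions vs
    the binomial expectation) are clipped to a sane range and averaged over
    informative sites.  Pooling shrinks the 1-2-df per-site estimate, which
    would otherwise inflate the Wald SE badly.
    """
    if meth.shape[1] < 2:
        return 0.0
    q = meth / total
    s2 = np.var(q, axis=1, ddof=1)
    h = np.mean(1.0 / total, axis=1)
    pc = np.clip(pooled_p, 0.05, 0.95)
    pv = pc * (1 - pc)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (s2 / pv - h) / (1.0 - h)
    informative = (pooled_p > 0.01) & (pooled_p < 0.99) & (h < 1.0)
    if not informative.any():
        return 0.0
    return float(np.mean(np.clip(phi[informative], -0.25, 1.0)))


def _window_bounds(pos: np.ndarray, bandwidth: float) -> tuple[np.ndarray, np.ndarray]:
    h = bandwidth / 2.0
    lo = np.searchsorted(pos, pos - h, side="left")
    hi = np.searchsorted(pos, pos + h, side="right")
    return lo, hi


def _window_sum(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    c = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    return c[hi] - c[lo]


def smooth_levels(matrix: MethylomeMatrix, group: str,
                  bandwidth: float = 500.0) -> np.ndarray:
    """Coverage-weighted boxcar-smoothed group methylation level per site.

    Pools methylated and total counts over all samples of ``group`` and all
    sites within +/- bandwidth/2 of each site; a site always includes
    itself.  NaN where the window has zero pooled coverage.
    """
    if bandwidth <= 0:
        raise ConfigError("bandwidth must be positive")
    cols = matrix.group_columns(group)
    meth = matrix.meth[:, cols].sum(axis=1).astype(float)
    total = matrix.total[:, cols].sum(axis=1).astype(float)
    out = np.full(matrix.n_sites, np.nan)
    for chrom, sl in matrix.chrom_slices().items():
        pos = matrix.sites["pos"].to_numpy()[sl].astype(float)
        lo, hi = _window_bounds(pos, bandwidth)
        mw = _window_sum(meth[sl], lo, hi)
        nw = _window_sum(total[sl], lo, hi)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[sl] = np.where(nw > 0, mw / nw, np.nan)
    return out


def test_sites(matrix: MethylomeMatrix, group_a: str, group_b: str,
               bandwidth: float = 500.0, phi_floor: float = PHI_FLOOR,
               ) -> pd.DataFrame:
    """Smoothed beta-binomial Wald test at every complete-coverage site.

    Restricts to sites covered in every sample of both groups, then returns
    one row per site: raw and smoothed group levels, smoothed difference,
    SE, Wald statistic and two-sided p-value.
    """
    if bandwidth <= 0:
        raise ConfigError("bandwidth must be positive")
    mask = group_complete_mask(matrix, [group_a, group_b])
    sub = matrix.subset_sites(mask)
    cols = {g: sub.group_columns(g) for g in (group_a, group_b)}

    n = sub.n_sites
    res = {
        "chrom": sub.sites["chrom"].to_numpy(),
        "pos": sub.sites["pos"].to_numpy(),
    }
    # shared site weights (total coverage over both groups): both smoothers
    # weight sites identically, so between-site baseline heterogeneity
    # cancels exactly from the smoothed difference
    both = np.concatenate([cols[group_a], cols[group_b]])
    w_site = sub.total[:, both].sum(axis=1).astype(float)
    smooth = {}
    var = {g: np.zeros(n) for g in cols}
    raw = {}
    for g, cc in cols.items():
        meth_g = sub.meth[:, cc].astype(float)
        tot_g = sub.total[:, cc].astype(float)
        pooled_m = meth_g.sum(axis=1)
        pooled_n = tot_g.sum(axis=1)
        raw[g] = pooled_m / pooled_n
        sm = np.empty(n)
        for chrom, sl in sub.chrom_slices().items():
            pos = sub.sites["pos"].to_numpy()[sl].astype(float)
            lo, hi = _window_bounds(pos, bandwidth)
            w = w_site[sl]
            sw = _window_sum(w, lo, hi)
            p = _window_sum(w * raw[g][sl], lo, hi) / sw
            sm[sl] = p
            # method-of-moments dispersion: per-site estimates from
            # per-sample raw proportions, pooled along the chromosome
            # (the per-site estimate at 2-3 samples is far too noisy alone)
            phi = max(
                _pooled_mom_phi(meth_g[sl], tot_g[sl], raw[g][sl]), phi_floor
            )
            # variance of the weighted smoother from per-site beta-binomial
            # variance of the group's raw level (per-site level in the
            # p(1-p) term, so between-site heterogeneity does not inflate it)
            pc = np.clip(raw[g][sl], P_CLIP, 1 - P_CLIP)
            pv = pc * (1 - pc)
            u = tot_g[sl] + (tot_g[sl] ** 2 - tot_g[sl]) * phi  # site x sample
            v_site = pv * u.sum(axis=1) / pooled_n[sl] ** 2
            var[g][sl] = _window_sum(w**2 * v_site, lo, hi) / sw**2
        smooth[g] = sm

    diff = smooth[group_a] - smooth[group_b]
    se = np.sqrt(var[group_a] + var[group_b])
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(se > 0, diff / se, 0.0)
    p_value = 2.0 * stats.norm.sf(np.abs(stat))
    p_value = np.where(diff == 0, 1.0, np.minimum(p_value, 1.0))
    res.update(
        {
            "raw_a": raw[group_a],
            "raw_b": raw[group_b],
            "smooth_a": smooth[group_a],
            "smooth_b": smooth[group_b],
            "diff": diff,
            "se": se,
            "stat": stat,
            "p_value": p_value,
        }
    )
    return pd.DataFrame(res)


# ---------------------------------------------------------------------------
# Candidate regions


def _max_valid_end(sig_idx: np.ndarray, g: np.ndarray) -> np.ndarray:
    """For each significant site u, the largest significant v with a valid run.

    A run [u, v] is valid iff g[v+1] >= g[u] where g(i) = #sig among the
    first i sites minus min_sig_fraction * i.
    """
    vals = g[sig_idx + 1]
    # suffix max of vals (nonincreasing as k grows when scanned from right)
    suff = np.maximum.accumulate(vals[::-1])[::-1]
    out = np.empty(len(sig_idx), dtype=np.int64)
    for k in range(len(sig_idx)):
        t = g[sig_idx[k]]
        # largest j >= k with vals[j] >= t; suff is nonincreasing in j
        lo, hi = k, len(sig_idx) - 1
        if suff[k] < t:  # cannot happen for j = k (site itself significant)
            out[k] = sig_idx[k]
            continue
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if suff[mid] >= t:
                lo = mid
            else:
                hi = mid - 1
        # walk left from lo until vals >= t (suff guarantees existence at <= lo)
        j = lo
        while vals[j] < t:
            j -= 1
        out[k] = sig_idx[j]
    return out


def call_candidate_regions(results: pd.DataFrame, p_threshold: float = 0.05,
                           max_gap: int = 100, min_sig_fraction: float = 0.5,
                           min_abs_diff: float = 0.15) -> pd.DataFrame:
    """Form candidate regions from per-site test results.

    A site is *significant* when ``p_value < p_threshold`` and its absolute
    smoothed difference is >= ``min_abs_diff`` (a DSS-style delta floor that
    keeps region boundaries from bleeding past true edges).  Candidates are
    maximal site runs bounded by significant sites with all consecutive-site
    gaps <= ``max_gap`` and significant fraction >= ``min_sig_fraction``;
    overlapping maximal runs are coalesced.
    """
    rows = []
    for chrom, sub in results.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        sub = sub.iloc[order]
        pos = pos[order]
        sig = (
            (sub["p_value"].to_numpy() < p_threshold)
            & (np.abs(sub["diff"].to_numpy()) >= min_abs_diff)
        )
        # blocks split where consecutive sites are further apart than max_gap
        splits = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for blk in np.split(np.arange(len(pos)), splits):
            bsig = sig[blk]
            if not bsig.any():
                continue
            # g(i) = #sig in first i sites - rho * i
            g = np.concatenate([[0.0], np.cumsum(bsig) - min_sig_fraction * np.arange(1, len(blk) + 1)])
            sig_idx = np.flatnonzero(bsig)
            ends = _max_valid_end(sig_idx, g)
            # keep containment-maximal windows, then merge overlaps
            windows = []
            best_end = -1
            for u, v in zip(sig_idx, ends):
                if v > best_end:
                    windows.append([u, v])
                    best_end = v
            merged = [windows[0]]
            for u, v in windows[1:]:
                if u <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], v)
                else:
                    merged.append([u, v])
            for u, v in merged:
                seg = sub.iloc[blk[u]: blk[v] + 1]
                rows.append(_candidate_row(chrom, seg))
    cols = ["chrom", "start", "end", "n_cpg", "n_sig", "mean_a", "mean_b",
            "mean_diff"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def _candidate_row(chrom, seg: pd.DataFrame) -> dict:
    raw_a = seg["raw_a"].to_numpy()
    raw_b = seg["raw_b"].to_numpy()
    return {
        "chrom": chrom,
        "start": int(seg["pos"].iloc[0]),
        "end": int(seg["pos"].iloc[-1]) + 1,
        "n_cpg": len(seg),
        "n_sig": int((seg["p_value"] < 0.05).sum()),
        "mean_a": float(np.mean(raw_a)),
        "mean_b": float(np.mean(raw_b)),
        "mean_diff": float(np.mean(raw_a - raw_b)),
    }


def filter_dmrs(candidates: pd.DataFrame, min_diff: float = 0.25,
                min_cpg: int = 4, min_len: int = 50,
                comparison: tuple[str, str] | None = None) -> pd.DataFrame:
    """Apply the region filter cascade and annotate direction.

    Keeps candidates with |mean per-site raw difference| >= ``min_diff``,
    ``n_cpg >= min_cpg`` and length >= ``min_len`` bp.  Direction is "gain"
    when the focal (first) group's mean exceeds the other group's.
    """
    c = candidates.copy()
    keep = (
        (np.abs(c["mean_diff"]) >= min_diff)
        & (c["n_cpg"] >= min_cpg)
        & ((c["end"] - c["start"]) >= min_len)
    )
    out = c[keep].reset_index(drop=True)
    out["direction"] = np.where(out["mean_diff"] > 0, "gain", "loss")
    out["comparison"] = (
        f"{comparison[0]}_vs_{comparison[1]}" if comparison else "A_vs_B"
    )
    return out


def call_dmrs(matrix: MethylomeMatrix, group_a: str, group_b: str,
              bandwidth: float = 500.0, p_threshold: float = 0.05,
              max_gap: int = 100, min_sig_fraction: float = 0.5,
              min_abs_diff: float = 0.15, min_diff: float = 0.25,
              min_cpg: int = 4, min_len: int = 50) -> pd.DataFrame:
    """End-to-end DMR calling between two populations of a filtered matrix."""
    results = test_sites(matrix, group_a, group_b, bandwidth=bandwidth)
    cand = call_candidate_regions(
        results, p_threshold=p_threshold, max_gap=max_gap,
        min_sig_fraction=min_sig_fraction, min_abs_diff=min_abs_diff,
    )
    return filter_dmrs(cand, min_diff=min_diff, min_cpg=min_cpg,
                       min_len=min_len, comparison=(group_a, group_b))


# ---------------------------------------------------------------------------
# Merging and summaries


def merge_dmr_sets(dmr_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of DMR sets; overlapping or bookended intervals coalesce.

    Each merged interval records the contributing comparisons and, per
    comparison, the direction and mean difference of its source DMRs.
    """
    frames = [d for d in dmr_sets if len(d)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "comparisons",
                                     "sources"])
    alld = pd.concat(frames, ignore_index=True)
    rows = []
    for chrom, sub in alld.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur = None
        for r in sub.itertuples():
            if cur is None or r.start > cur["end"]:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": int(r.start), "end": int(r.end),
                       "sources": []}
            cur["end"] = max(cur["end"], int(r.end))
            cur["sources"].append(
                {
                    "comparison": r.comparison,
                    "direction": r.direction,
                    "mean_diff": float(r.mean_diff),
                }
            )
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows)
    out["comparisons"] = out["sources"].map(
        lambda ss: tuple(sorted({s["comparison"] for s in ss}))
    )
    return out[["chrom", "start", "end", "comparisons", "sources"]]


def summarize_dmrs(dmrs: pd.DataFrame) -> dict:
    """Descriptive statistics of a DMR set (zeros for an empty set)."""
    if len(dmrs) == 0:
        return {"n": 0, "length_median": 0, "length_range": (0, 0),
                "n_cpg_median": 0, "n_cpg_range": (0, 0),
                "gain_fraction": 0.0, "median_gain_methylation": 0.0}
    lengths = (dmrs["end"] - dmrs["start"]).to_numpy()
    ncpg = dmrs["n_cpg"].to_numpy()
    gain = dmrs["direction"] == "gain"
    med_gain = float(np.median(dmrs.loc[gain, "mean_a"])) if gain.any() else 0.0
    return {
        "n": int(len(dmrs)),
        "length_median": float(np.median(lengths)),
        "length_range": (int(lengths.min()), int(lengths.max())),
        "n_cpg_median": float(np.median(ncpg)),
        "n_cpg_range": (int(ncpg.min()), int(ncpg.max())),
        "gain_fraction": float(gain.mean()),
        "median_gain_methylation": med_gain,
    }


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6+ output: name, score=round(100*|diff|), strand '.', extra columns."""
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": [f"DMR_{i}" for i in range(len(dmrs))],
            "score": np.round(100 * np.abs(dmrs["mean_diff"])).astype(int),
            "strand": ".",
            "n_cpg": dmrs["n_cpg"],
            "mean_a": dmrs["mean_a"].round(4),
            "mean_b": dmrs["mean_b"].round(4),
            "direction": dmrs["direction"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
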