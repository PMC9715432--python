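"""Shuffle-based genomic-feature enrichment and exact set-overlap tests.

The expected number of DMRs overlapping a feature class is obtained by
placing each DMR, length preserved, uniformly at random across the genome
(chromosome chosen proportional to its length) and counting overlaps, over
many iterations.  The observed/expected ratio is tested with a one-sample
t-test of the shuffle counts against the observed count, and contingency of
observed vs expected across comparisons with a chi-squared test.  DMR x DEG
set overlap uses the exact hypergeometric distribution with a
representation factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv


@dataclass
class EnrichmentResult:
    feature: str
    observed: int
    expected_mean: float
    expected_sd: float
    ratio: float | None          # None when expected_mean == 0
    t_p: float | None
    n_iter: int
    expected_counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "observed": self.observed,
            "expected_mean": self.expected_mean,
            "expected_sd": self.expected_sd,
            "ratio": self.ratio,
            "t_p": self.t_p,
            "n_iter": self.n_iter,
        }


def shuffle_intervals(dmrs: pd.DataFrame, chrom_sizes: dict[str, int],
                      n_iter: int = 1000, seed: int = 0,
                      exclude: pd.DataFrame | None = None) -> list[pd.DataFrame]:
    """Place each interval uniformly at random across the genome, n_iter times.

    Chromosomes are chosen with probability proportional to their length
    among those long enough to hold the interval; the start is uniform such
    that the interval fits.  Placements may overlap each other.  An optional
    ``exclude`` BED removes placements overlapping it (resampled).
    """
    rng = np.random.default_rng(seed)
    lengths = (dmrs["end"] - dmrs["start"]).to_numpy(dtype=np.int64)
    chroms = np.array(list(chrom_sizes))
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if lengths.size and lengths.max() > sizes.max():
        raise ValueError("an interval is longer than every chromosome")
    out = []
    for _ in range(n_iter):
        c_idx, starts = _place_once(rng, lengths, sizes)
        df = pd.DataFrame(
            {"chrom": chroms[c_idx], "start": starts, "end": starts + lengths}
        )
        if exclude is not None and len(exclude):
            bad = iv.overlaps_any_by_chrom(df, exclude)
            tries = 0
            while bad.any() and tries < 50:
                c2, s2 = _place_once(rng, lengths[bad], sizes)
                df.loc[bad, "chrom"] = chroms[c2]
                df.loc[bad, "start"] = s2
                df.loc[bad, "end"] = s2 + lengths[bad]
                bad = iv.overlaps_any_by_chrom(df, exclude)
                tries += 1
        out.append(df)
    return out


def _place_once(rng, lengths, sizes):
    fits = sizes[None, :] >= lengths[:, None]           # (n, n_chrom)
    w = np.where(fits, sizes[None, :], 0).astype(float)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(len(lengths))
    c_idx = (np.cumsum(w, axis=1) < u[:, None]).sum(axis=1)
    max_start = sizes[c_idx] - lengths
    starts = rng.integers(0, max_start + 1)
    return c_idx, starts


def count_overlapping(dmrs: pd.DataFrame, feature: pd.DataFrame) -> int:
    """Number of query intervals overlapping the feature set by >= 1 bp."""
    if len(dmrs) == 0 or len(feature) == 0:
        return 0
    return int(iv.overlaps_any_by_chrom(dmrs, feature).sum())


def observed_expected(dmrs: pd.DataFrame, feature: pd.DataFrame,
                      chrom_sizes: dict[str, int], n_iter: int = 1000,
                      seed: int = 0, feature_name: str = "feature",
                      shuffles: list[pd.DataFrame] | None = None,
                      ) -> EnrichmentResult:
    """Observed vs shuffle-expected DMR counts for one feature class.

    Pass precomputed ``shuffles`` to reuse the same placements across
    feature classes (cheaper, and mirrors shuffling coordinates once per
    iteration rather than per feature).
    """
    if shuffles is None:
        shuffles = shuffle_intervals(dmrs, chrom_sizes, n_iter=n_iter, seed=seed)
    if not shuffles:
        raise ValueError("need >= 1 shuffle iteration")
    observed = count_overlapping(dmrs, feature)
    exp = np.array([count_overlapping(s, feature) for s in shuffles], dtype=float)
    mean, sd = float(exp.mean()), float(exp.std(ddof=1)) if len(exp) > 1 else 0.0
    ratio = observed / mean if mean > 0 else None
    if np.all(exp == exp[0]):
        t_p = 1.0 if exp[0] == observed else 0.0
    else:
        t_p = float(stats.ttest_1samp(exp, observed).pvalue)
    return EnrichmentResult(
        feature=feature_name, observed=observed, expected_mean=mean,
        expected_sd=sd, ratio=ratio, t_p=t_p, n_iter=len(shuffles),
        expected_counts=exp,
    )


def chi2_across_comparisons(results: dict[str, EnrichmentResult]) -> float:
    """Chi-squared p for the observed/expected contingency across comparisons.

    Rows are comparison groups, columns the observed and expected-mean
    counts for one feature class.
    """
    table = np.array(
        [[r.observed, r.expected_mean] for r in results.values()], dtype=float
    )
    if table.shape[0] < 2 or np.any(table.sum(axis=1) == 0):
        raise ValueError("need >= 2 comparisons with nonzero counts")
    return float(stats.chi2_contingency(table)[1])


def hypergeom_overlap(n_universe: int, n_set_a: int, n_set_b: int,
                      n_overlap: int, method: str = "min-likelihood",
                      ) -> tuple[float, float]:
    """Representation factor and two-sided exact hypergeometric p-value.

    The representation factor is ``n_overlap / (n_set_a * n_set_b /
    n_universe)``.  Two-sided p by the minimum-likelihood rule (sum of all
    outcome probabilities <= the observed outcome's), or ``method="double"``
    for twice the smaller tail capped at 1.
    """
    if not (0 <= n_overlap <= min(n_set_a, n_set_b) <= n_universe):
        raise ValueError("inconsistent overlap counts")
    if n_set_a + n_set_b - n_overlap > n_universe:
        raise ValueError("sets exceed universe")
    if n_universe == 0:
        raise ValueError("empty universe")
    expected = n_set_a * n_set_b / n_universe
    rf = n_overlap / expected if expected > 0 else float("inf")
    dist = stats.hypergeom(M=n_universe, n=n_set_a, N=n_set_b)
    k_min = max(0, n_set_a + n_set_b - n_universe)
    k_max = min(n_set_a, n_set_b)
    ks = np.arange(k_min, k_max + 1)
    pmf = dist.pmf(ks)
    p_obs = dist.pmf(n_overlap)
    if method == "min-likelihood":
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    elif method == "double":
        lower = float(dist.cdf(n_overlap))
        upper = float(dist.sf(n_overlap - 1))
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rf), float(min(p, 1.0))
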