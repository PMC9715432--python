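"""Cohort-level descriptive and inferential statistics.

PCA of sample methylomes (centred, unit-scaled), one-way MANOVA on PC
scores via Pillai's trace, Welch's heteroscedastic ANOVA with Games-Howell
all-pairs post-hoc tests, percentile-bootstrap mean-difference CIs,
correlation-based complete-linkage clustering, and the cross-platform
sample x DMR mean-methylation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .methylome_io import MethylomeMatrix


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame           # samples x components
    loadings: np.ndarray           # sites x components
    variance_explained: np.ndarray


def pca_methylome(matrix: MethylomeMatrix, n_components: int | None = None,
                  ) -> PCAResult:
    """PCA of the sample x site methylation-level matrix (centred and scaled).

    Uses only sites covered in every sample; zero-variance sites are dropped
    (unit scaling is undefined there).  Component signs follow the
    largest-absolute-loading-positive convention.
    """
    levels = matrix.levels()
    complete = ~np.isnan(levels).any(axis=1)
    x = levels[complete].T                       # samples x sites
    if x.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    sd = x.std(axis=0, ddof=1)
    var_ok = sd > 0
    if not var_ok.any():
        raise ValueError("all sites have zero variance across samples")
    x = x[:, var_ok]
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = n_components or min(z.shape) - 0
    k = min(k, len(s))
    # sign convention: largest-|loading| positive per component
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    var = s**2 / (z.shape[0] - 1)
    ve = var[:k] / var.sum()
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=matrix.samples,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        loadings=vt[:k].T,
        variance_explained=ve,
    )


# ---------------------------------------------------------------------------
# MANOVA (Pillai's trace)


def manova_pc_scores(scores: pd.DataFrame, labels,
                     n_components: int = 2) -> tuple[float, int, int, float]:
    """One-way MANOVA (Pillai's trace with F approximation) on PC scores.

    Returns (F, df1, df2, p).
    """
    y = np.asarray(scores.iloc[:, :n_components], dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    g = len(groups)
    n, p = y.shape
    if g < 2:
        raise ValueError("need >= 2 groups")
    for grp in groups:
        if (labels == grp).sum() < p:
            raise ValueError(
                f"group {grp!r} has fewer samples than components"
            )
    grand = y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for grp in groups:
        sub = y[labels == grp]
        m = sub.mean(axis=0)
        H += len(sub) * np.outer(m - grand, m - grand)
        E += (sub - m).T @ (sub - m)
    eig = np.linalg.eigvals(np.linalg.solve(H + E, H)).real
    V = float(np.sum(eig))
    s = min(p, g - 1)
    m_par = (abs(p - g + 1) - 1) / 2.0
    n_par = (n - g - p - 1) / 2.0
    df1 = int(s * (2 * m_par + s + 1))
    df2 = int(s * (2 * n_par + s + 1))
    F = ((2 * n_par + s + 1) / (2 * m_par + s + 1)) * (V / (s - V))
    p_value = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p_value


# ---------------------------------------------------------------------------
# Welch ANOVA + Games-Howell


def welch_anova(values, labels) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA: (F, df1, df2, p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ni, mi, vi = [], [], []
    for grp in groups:
        x = values[labels == grp]
        if len(x) < 2:
            raise ValueError(f"group {grp!r} needs >= 2 values")
        ni.append(len(x))
        mi.append(x.mean())
        vi.append(x.var(ddof=1))
    ni = np.array(ni, dtype=float)
    mi = np.array(mi)
    vi = np.array(vi)
    if np.all(vi == 0):
        if np.all(mi == mi[0]):
            return 0.0, float(k - 1), float("inf"), 1.0
        return float("inf"), float(k - 1), float("inf"), 0.0
    wi = ni / vi
    mw = np.sum(wi * mi) / np.sum(wi)
    a = np.sum(wi * (mi - mw) ** 2) / (k - 1)
    lam = 3.0 * np.sum((1 - wi / np.sum(wi)) ** 2 / (ni - 1)) / (k**2 - 1)
    F = a / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df1 = float(k - 1)
    df2 = 1.0 / lam
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, float(df2), p


def games_howell(values, labels) -> pd.DataFrame:
    """Games-Howell all-pairs comparisons (studentized-range adjusted p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    k = len(groups)
    stats_by = {}
    for grp in groups:
        x = values[labels == grp]
        stats_by[grp] = (len(x), x.mean(), x.var(ddof=1))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = groups[i], groups[j]
            n1, m1, v1 = stats_by[g1]
            n2, m2, v2 = stats_by[g2]
            se2 = v1 / n1 + v2 / n2
            diff = m1 - m2
            if se2 == 0:
                t = 0.0 if diff == 0 else np.inf
                df = n1 + n2 - 2.0
            else:
                t = diff / np.sqrt(se2)
                df = se2**2 / (
                    (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
                )
            q = abs(t) * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, df)) if np.isfinite(t) else (
                1.0 if diff == 0 else 0.0
            )
            rows.append(
                {"group1": g1, "group2": g2, "mean_diff": diff, "t": t,
                 "df": df, "p_adj": min(p, 1.0)}
            )
    return pd.DataFrame(rows)


def welch_games_howell(values, labels) -> dict:
    """Welch's ANOVA followed by Games-Howell post-hoc pairwise tests."""
    F, df1, df2, p = welch_anova(values, labels)
    return {
        "welch_F": F, "df1": df1, "df2": df2, "p_value": p,
        "pairwise": games_howell(values, labels),
    }


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_mean_diff(a, b, n_boot: int = 5000, seed: int = 0,
                        ) -> tuple[float, tuple[float, float]]:
    """mean(a) - mean(b) with a 95% percentile-bootstrap CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    rng = np.random.default_rng(seed)
    diff = float(a.mean() - b.mean())
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    boots = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return diff, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Correlation clustering


def correlation_cluster(data: pd.DataFrame) -> dict:
    """Complete-linkage clustering of samples.

    ``data`` is features x samples.  Pairwise Spearman correlations between
    samples (pairwise-complete over NaN), Euclidean distances between the
    rows of the correlation matrix, complete linkage.  Returns the linkage
    matrix, leaf order, correlation matrix and a Newick string.
    """
    const = data.nunique(dropna=True) <= 1
    if const.any():
        raise ValueError(
            f"constant sample vector(s): {list(data.columns[const])}"
        )
    corr = data.corr(method="spearman")
    if corr.isna().any().any():
        bad = corr.columns[corr.isna().any()].tolist()
        raise ValueError(f"undefined correlations involving sample(s) {bad}")
    dist = pdist(corr.to_numpy(), metric="euclidean")
    z = hierarchy.linkage(dist, method="complete")
    order = hierarchy.leaves_list(z)
    leaves = [corr.columns[i] for i in order]
    return {
        "linkage": z,
        "leaf_order": leaves,
        "correlation": corr,
        "newick": linkage_to_newick(z, list(corr.columns)),
    }


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (merge heights as depths)."""
    n = len(labels)

    def height(i):
        return 0.0 if i < n else z[i - n, 2]

    def render(i):
        if i < n:
            return labels[i]
        a, b, h = int(z[i - n, 0]), int(z[i - n, 1]), z[i - n, 2]
        return (
            f"({render(a)}:{h - height(a):.6g},{render(b)}:{h - height(b):.6g})"
        )

    return render(n + len(z) - 1) + ";"


# ---------------------------------------------------------------------------
# RRBS <-> WGBS cross-validation matrix


def cross_platform_matrix(matrix: MethylomeMatrix, dmrs: pd.DataFrame,
                          ) -> pd.DataFrame:
    """Sample x DMR mean methylation over covered sites; NaN when uncovered."""
    levels = matrix.levels()
    slices = matrix.chrom_slices()
    pos_all = matrix.sites["pos"].to_numpy()
    cols = {}
    for idx, r in dmrs.reset_index(drop=True).iterrows():
        name = f"DMR_{idx}"
        sl = slices.get(r["chrom"])
        if sl is None:
            cols[name] = np.full(len(matrix.samples), np.nan)
            continue
        pos = pos_all[sl]
        lo = np.searchsorted(pos, r["start"])
        hi = np.searchsorted(pos, r["end"])
        with np.errstate(invalid="ignore"):
            cols[name] = np.nanmean(levels[sl][lo:hi], axis=0) if hi > lo else (
                np.full(len(matrix.samples), np.nan)
            )
    return pd.DataFrame(cols, index=matrix.samples)
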