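"""Methylome-transcriptome integration.

Differential expression is tested per gene with a Wald statistic on the
difference of group means of log2(TPM+1) using a pooled-variance standard
error, Benjamini-Hochberg adjusted across genes; a gene is a DEG when
q < 0.05, |log2FC| >= 1.5 and its maximal expression reaches >= 10 TPM in
at least one sample.  Genes are binned into OFF (mean TPM < 5) plus four
equal-count ON expression categories for methylation metaprofiles spanning
TSS - 2 kbp to TES + 2 kbp, and promoter methylation is correlated with
transcription by Spearman rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methylome_io import MethylomeMatrix


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM abundances with population labels per sample."""

    tpm: pd.DataFrame              # index: gene_id; columns: sample ids
    populations: dict[str, str]

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be nonnegative")
        if self.tpm.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        missing = [s for s in self.tpm.columns if s not in self.populations]
        if missing:
            raise ValueError(f"samples without population label: {missing}")

    def samples_of(self, population: str) -> list[str]:
        cols = [s for s in self.tpm.columns if self.populations[s] == population]
        if not cols:
            raise KeyError(f"no samples for population {population!r}")
        return cols

    def to_tsv(self, path) -> None:
        self.tpm.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, populations: dict[str, str]) -> "ExpressionMatrix":
        tpm = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tpm, populations)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment with monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(expr: ExpressionMatrix, group_a: str, group_b: str,
              alpha: float = 0.05, min_abs_log2fc: float = 1.5,
              min_tpm: float = 10.0, se_floor: float = 1e-8) -> pd.DataFrame:
    """Wald test on group means of log2(TPM+1) with pooled-variance SE.

    Returns one row per gene with log2fc (A minus B), p, q, max_tpm and the
    ``passes`` flag combining q < alpha, |log2fc| >= min_abs_log2fc and
    max_tpm >= min_tpm.
    """
    a_cols = expr.samples_of(group_a)
    b_cols = expr.samples_of(group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    la = np.log2(expr.tpm[a_cols].to_numpy() + 1.0)
    lb = np.log2(expr.tpm[b_cols].to_numpy() + 1.0)
    na, nb = la.shape[1], lb.shape[1]
    diff = la.mean(axis=1) - lb.mean(axis=1)
    sp2 = ((na - 1) * la.var(axis=1, ddof=1) + (nb - 1) * lb.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    zero_var = se == 0
    stat = diff / np.maximum(se, se_floor)
    p = 2.0 * stats.norm.sf(np.abs(stat))
    p = np.where(zero_var & (diff == 0), 1.0, p)
    q = bh_adjust(p)
    max_tpm = expr.tpm[a_cols + b_cols].to_numpy().max(axis=1)
    out = pd.DataFrame(
        {
            "gene_id": expr.tpm.index,
            "comparison": f"{group_a}_vs_{group_b}",
            "log2fc": diff,
            "p_value": p,
            "q_value": q,
            "max_tpm": max_tpm,
        }
    )
    out["passes"] = (
        (out["q_value"] < alpha)
        & (np.abs(out["log2fc"]) >= min_abs_log2fc)
        & (out["max_tpm"] >= min_tpm)
    )
    return out


def call_degs_all_pairs(expr: ExpressionMatrix, **kwargs) -> pd.DataFrame:
    """DEG calls for every ordered population pair (later vs earlier)."""
    pops = list(dict.fromkeys(expr.populations[s] for s in expr.tpm.columns))
    frames = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            frames.append(call_degs(expr, pops[j], pops[i], **kwargs))
    return pd.concat(frames, ignore_index=True)


def expression_bins(expr: ExpressionMatrix, off_threshold: float = 5.0,
                    n_on_bins: int = 4, population: str | None = None,
                    ) -> pd.Series:
    """OFF (mean TPM < threshold) plus equal-count ON quantile categories."""
    cols = expr.samples_of(population) if population else list(expr.tpm.columns)
    mean_tpm = expr.tpm[cols].mean(axis=1)
    on = mean_tpm >= off_threshold
    if on.sum() < n_on_bins:
        raise ValueError(
            f"degenerate binning: only {int(on.sum())} ON genes for "
            f"{n_on_bins} bins"
        )
    labels = [f"ON_{i + 1}" for i in range(n_on_bins)]
    cats = pd.Series("OFF", index=expr.tpm.index, dtype=object)
    ranks = mean_tpm[on].rank(method="first")
    cats.loc[on] = pd.qcut(ranks, n_on_bins, labels=labels).astype(str)
    order = ["OFF"] + labels
    return pd.Series(pd.Categorical(cats, categories=order, ordered=True),
                     index=expr.tpm.index, name="category")


def metaprofile(matrix: MethylomeMatrix, genes: pd.DataFrame,
                categories: pd.Series, flank: int = 2000,
                n_body_bins: int = 60, n_flank_bins: int = 20,
                ) -> pd.DataFrame:
    """Average methylation profile TSS-flank -> TES+flank per gene category.

    Fixed-width bins on the flanks, length-normalised bins on gene bodies,
    strand-flipped to a uniform 5'->3' orientation.  Cell (category, bin) is
    the mean over genes of the gene's per-bin mean site methylation; bins a
    gene has no covered site in are ignored for that gene.
    """
    n_bins = 2 * n_flank_bins + n_body_bins
    levels = matrix.levels()
    with np.errstate(invalid="ignore"):
        site_level = np.nanmean(levels, axis=1)
    slices = matrix.chrom_slices()
    pos_all = matrix.sites["pos"].to_numpy()

    cat_names = [c for c in categories.cat.categories]
    sums = {c: np.zeros(n_bins) for c in cat_names}
    counts = {c: np.zeros(n_bins) for c in cat_names}

    for g in genes.itertuples():
        cat = categories.get(g.gene_id)
        if cat is None or (isinstance(cat, float) and np.isnan(cat)):
            continue
        sl = slices.get(g.chrom)
        if sl is None:
            continue
        pos = pos_all[sl]
        lo = np.searchsorted(pos, g.start - flank)
        hi = np.searchsorted(pos, g.end + flank)
        if hi <= lo:
            continue
        p = pos[lo:hi].astype(float)
        v = site_level[sl][lo:hi]
        ok = ~np.isnan(v)
        if not ok.any():
            continue
        p, v = p[ok], v[ok]
        bins = _profile_bins(p, g.start, g.end, flank, n_flank_bins, n_body_bins)
        if g.strand == "-":
            bins = n_bins - 1 - bins
        gene_sum = np.bincount(bins, weights=v, minlength=n_bins)
        gene_n = np.bincount(bins, minlength=n_bins)
        has = gene_n > 0
        sums[str(cat)][has] += gene_sum[has] / gene_n[has]
        counts[str(cat)][has] += 1

    rows = {}
    for c in cat_names:
        with np.errstate(invalid="ignore"):
            rows[c] = np.where(counts[c] > 0, sums[c] / counts[c], np.nan)
    out = pd.DataFrame(rows).T
    out.index.name = "category"
    out.columns.name = "bin"
    return out


def _profile_bins(p, start, end, flank, n_flank, n_body):
    """Plus-strand bin index per site position (0 .. 2*n_flank+n_body-1)."""
    bins = np.empty(len(p), dtype=np.int64)
    up = p < start
    down = p >= end
    body = ~up & ~down
    w = flank / n_flank
    bins[up] = np.clip(((p[up] - (start - flank)) // w).astype(np.int64), 0, n_flank - 1)
    L = max(end - start, 1)
    bins[body] = n_flank + np.clip(
        ((p[body] - start) * n_body // L).astype(np.int64), 0, n_body - 1
    )
    bins[down] = n_flank + n_body + np.clip(
        ((p[down] - end) // w).astype(np.int64), 0, n_flank - 1
    )
    return bins


def promoter_methylation(matrix: MethylomeMatrix, promoters: pd.DataFrame,
                         ) -> pd.Series:
    """Per-gene mean promoter methylation (mean over sites of sample-mean levels)."""
    with np.errstate(invalid="ignore"):
        site_level = np.nanmean(matrix.levels(), axis=1)
    slices = matrix.chrom_slices()
    pos_all = matrix.sites["pos"].to_numpy()
    out = {}
    for r in promoters.itertuples():
        sl = slices.get(r.chrom)
        if sl is None:
            continue
        pos = pos_all[sl]
        lo = np.searchsorted(pos, r.start)
        hi = np.searchsorted(pos, r.end)
        vals = site_level[sl][lo:hi]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            out[r.gene_id] = float(vals.mean())
    return pd.Series(out, name="promoter_methylation")


def promoter_meth_expr_correlation(matrix: MethylomeMatrix,
                                   expr: ExpressionMatrix,
                                   promoters: pd.DataFrame,
                                   ) -> tuple[float, float]:
    """Spearman rho and p between promoter methylation and mean log2(TPM+1)."""
    meth = promoter_methylation(matrix, promoters)
    expr_mean = np.log2(expr.tpm + 1.0).mean(axis=1)
    common = meth.index.intersection(expr_mean.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes with both promoter methylation and expression")
    x = meth.loc[common].to_numpy()
    y = expr_mean.loc[common].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def deg_dmr_crosstab(deg_calls: pd.DataFrame, dmr_assignments: pd.DataFrame,
                     universe: list[str] | None = None) -> dict:
    """Counts feeding the exact hypergeometric DEG x promoter-DMR test.

    ``universe`` defaults to all genes in ``deg_calls``.  Also reports the
    breakdown of DEG-associated DMR assignments by class; a DEG counts once
    per class it has >= 1 associated DMR in.
    """
    if universe is None:
        universe = list(pd.unique(deg_calls["gene_id"]))
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    degs = set(deg_calls.loc[deg_calls["passes"], "gene_id"]) & universe_set
    prom = dmr_assignments[dmr_assignments["assignment"] == "promoter"]
    prom_genes = set(prom["gene_id"]) & universe_set
    overlap = degs & prom_genes

    by_class = {}
    deg_assign = dmr_assignments[dmr_assignments["gene_id"].isin(degs)]
    for klass in ("promoter", "gene_body", "intergenic"):
        by_class[klass] = int(
            deg_assign.loc[deg_assign["assignment"] == klass, "gene_id"].nunique()
        )
    return {
        "n_universe": len(universe_set),
        "n_deg": len(degs),
        "n_promoter_dmr_genes": len(prom_genes),
        "n_overlap": len(overlap),
        "deg_class_breakdown": by_class,
    }
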