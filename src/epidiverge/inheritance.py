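"""Fixed vs reset classification of wild DMRs in a common-garden generation.

A wild DMR is *fixed* when the region-level Wald test on the common-garden
cohort is significant (two-sided p < 0.05), in the same methylation
direction as in the wild, and direction-consistent across every
common-garden sample of both groups; otherwise it is *reset*.  DMRs with no
covered common-garden CpG are *untestable* and excluded from proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmr_caller import wald_test
from .methylome_io import MethylomeMatrix
from .population_stats import bootstrap_mean_diff


def _region_counts(matrix: MethylomeMatrix, chrom: str, start: int, end: int,
                   slices: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample methylated/total counts aggregated over a region's CpGs."""
    sl = (slices if slices is not None else matrix.chrom_slices()).get(chrom)
    if sl is None:
        z = np.zeros(len(matrix.samples), dtype=np.int64)
        return z, z.copy()
    pos = matrix.sites["pos"].to_numpy()[sl]
    lo = np.searchsorted(pos, start)
    hi = np.searchsorted(pos, end)
    meth = matrix.meth[sl][lo:hi].sum(axis=0)
    total = matrix.total[sl][lo:hi].sum(axis=0)
    return meth, total


def _comparison_groups(comparison: str) -> tuple[str, str]:
    a, b = comparison.split("_vs_")
    return a, b


def classify_fixed_reset(wild_dmrs: pd.DataFrame, cg_matrix: MethylomeMatrix,
                         alpha: float = 0.05, phi_floor: float = 1e-3,
                         ) -> pd.DataFrame:
    """Label merged wild DMRs fixed/reset/untestable from common-garden counts.

    ``wild_dmrs`` is the merged-DMR frame from :func:`merge_dmr_sets` (one
    row per merged interval with its contributing ``sources``).  Each
    contributing comparison is re-tested on counts aggregated over the
    region's CpGs per common-garden sample; the merged DMR is fixed when any
    contributing comparison re-tests significant with the wild direction and
    per-sample direction consistency.
    """
    slices = cg_matrix.chrom_slices()
    rows = []
    for idx, r in wild_dmrs.reset_index(drop=True).iterrows():
        meth, total = _region_counts(cg_matrix, r["chrom"], r["start"],
                                     r["end"], slices)
        sources = r["sources"] if "sources" in r else [
            {"comparison": r["comparison"], "direction": r["direction"],
             "mean_diff": r.get("mean_diff", np.nan)}
        ]
        label, best_p, best_dir, tested = "untestable", np.nan, "none", False
        for src in sources:
            ga, gb = _comparison_groups(src["comparison"])
            ca = cg_matrix.group_columns(ga)
            cb = cg_matrix.group_columns(gb)
            ta, tb = total[ca], total[cb]
            if not (ta > 0).any() or not (tb > 0).any():
                continue
            tested = True
            diff, stat, p = wald_test(meth[ca], ta, meth[cb], tb,
                                      phi_floor=phi_floor)
            cg_dir = "gain" if diff > 0 else ("loss" if diff < 0 else "none")
            consistent = _direction_consistent(meth[ca], ta, meth[cb], tb)
            if not consistent and cg_dir != "none":
                cg_dir_label = "mixed"
            else:
                cg_dir_label = cg_dir
            is_fixed = (
                p < alpha and cg_dir == src["direction"] and consistent
            )
            if np.isnan(best_p) or p < best_p:
                best_p, best_dir = p, cg_dir_label
            if is_fixed:
                label = "fixed"
                best_p, best_dir = p, cg_dir_label
                break
        if tested and label != "fixed":
            label = "reset"
        rows.append(
            {
                "dmr_index": idx,
                "chrom": r["chrom"],
                "start": int(r["start"]),
                "end": int(r["end"]),
                "cg_p_value": best_p,
                "cg_direction": best_dir,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def _direction_consistent(ma, ta, mb, tb) -> bool:
    """Every sample's region mean sits on its group's side of the other group."""
    ca = ta > 0
    cb = tb > 0
    pa = ma[ca].sum() / ta[ca].sum()
    pb = mb[cb].sum() / tb[cb].sum()
    d = pa - pb
    if d == 0:
        return False
    qa = ma[ca] / ta[ca]
    qb = mb[cb] / tb[cb]
    return bool(np.all((qa - pb) * d > 0) and np.all((pa - qb) * d > 0))


def inheritance_proportions(calls: pd.DataFrame) -> tuple[float, float]:
    """(fraction fixed, fraction reset) over testable calls; they sum to 1."""
    testable = calls[calls["label"].isin(["fixed", "reset"])]
    if len(testable) == 0:
        raise ValueError("no testable inheritance calls")
    f = float((testable["label"] == "fixed").mean())
    return f, 1.0 - f


def compare_lengths(fixed_lengths, reset_lengths, n_boot: int = 5000,
                    seed: int = 0) -> dict:
    """Medians and bootstrap CI for mean(reset) - mean(fixed) length.

    Percentile bootstrap with ``n_boot`` resamples of each set.
    """
    fixed = np.asarray(fixed_lengths, dtype=float)
    reset = np.asarray(reset_lengths, dtype=float)
    if fixed.size == 0:
        raise ValueError("fixed length set is empty")
    if reset.size == 0:
        raise ValueError("reset length set is empty")
    mean_diff, ci = bootstrap_mean_diff(reset, fixed, n_boot=n_boot, seed=seed)
    return {
        "median_fixed": float(np.median(fixed)),
        "median_reset": float(np.median(reset)),
        "mean_diff": mean_diff,
        "ci95": ci,
    }


def deg_inheritance_crosstab(deg_calls: pd.DataFrame,
                             dmr_assignments: pd.DataFrame,
                             calls: pd.DataFrame) -> dict:
    """Fractions of DMR-associated DEGs linked to reset vs fixed DMRs.

    A DEG counts once per inheritance class in which it has >= 1 associated
    DMR (a gene with both a fixed and a reset DMR counts in both), so the
    two fractions may sum to more than 1.  Fractions are over DEGs with any
    DMR association.
    """
    degs = set(deg_calls.loc[deg_calls["passes"], "gene_id"])
    label_by_dmr = calls.set_index("dmr_index")["label"]
    assoc = dmr_assignments[dmr_assignments["gene_id"].isin(degs)].copy()
    assoc["label"] = assoc["dmr_index"].map(label_by_dmr)
    assoc = assoc[assoc["label"].isin(["fixed", "reset"])]
    genes_any = assoc["gene_id"].nunique()
    if genes_any == 0:
        return {"n_deg_associated": 0, "fraction_reset": 0.0,
                "fraction_fixed": 0.0}
    n_reset = assoc.loc[assoc["label"] == "reset", "gene_id"].nunique()
    n_fixed = assoc.loc[assoc["label"] == "fixed", "gene_id"].nunique()
    return {
        "n_deg_associated": int(genes_any),
        "fraction_reset": n_reset / genes_any,
        "fraction_fixed": n_fixed / genes_any,
    }
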