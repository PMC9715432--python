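"""End-to-end orchestration: simulate -> ingest -> DMRs -> annotate ->
enrich -> DEGs -> integrate -> inheritance -> cohort stats.

`run_pipeline` executes the stages in dependency order from a single
simulation config, writes every stage's outputs under an output directory
and returns a machine-readable manifest (also written as JSON).
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import __version__
from . import annotation as ann
from . import dmr_caller as dc
from . import enrichment as enr
from . import expression_integration as ei
from . import inheritance as inh
from . import methylome_io as mio
from . import population_stats as ps
from .config import SimulationConfig
from .synthetic_data import simulate_study


def _write_cohort(matrix, out_dir, name):
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in matrix.samples:
        path = os.path.join(out_dir, f"{s}.cov")
        mio.write_bismark_cov(matrix.sample_table(s), path)
        rows.append({"sample_id": s, "population": matrix.populations[s],
                     "path": f"{name}/{s}.cov"})
    sheet = pd.DataFrame(rows)
    sheet_path = os.path.join(os.path.dirname(out_dir), f"{name}_samples.tsv")
    sheet.to_csv(sheet_path, sep="\t", index=False)
    return sheet_path


def run_pipeline(config: SimulationConfig, out_dir, n_shuffle: int = 1000,
                 ) -> dict:
    """Run the full synthetic study and analysis; return the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"tool": "epidiverge", "version": __version__,
                "seed": int(config.seed), "config": config.to_dict(),
                "outputs": {}, "summary": {}}
    out = manifest["outputs"]

    # -- simulate -----------------------------------------------------------
    study = simulate_study(config)
    genome, truth = study["genome"], study["truth"]
    out["genome"] = genome.write_bed_files(os.path.join(out_dir, "genome"))
    out["wild_sheet"] = _write_cohort(study["wild"], os.path.join(out_dir, "wild"), "wild")
    out["cg_sheet"] = _write_cohort(
        study["common_garden"], os.path.join(out_dir, "common_garden"), "common_garden"
    )
    out["tpm"] = os.path.join(out_dir, "tpm.tsv")
    study["expression"].to_tsv(out["tpm"])
    out["truth"] = os.path.join(out_dir, "truth.json")
    truth.to_json(out["truth"])

    # -- DMRs ---------------------------------------------------------------
    wild = mio.filter_coverage(study["wild"])
    pops = config.population_names
    dmr_sets = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[j], pops[i]
            dmrs = dc.call_dmrs(wild, a, b)
            path = os.path.join(out_dir, f"dmrs_{a}_vs_{b}.bed")
            dc.write_dmr_bed(dmrs, path)
            out[f"dmrs_{a}_vs_{b}"] = path
            dmr_sets.append(dmrs)
    merged = dc.merge_dmr_sets(dmr_sets)
    manifest["summary"]["dmrs"] = {
        f"{d['comparison'].iloc[0] if len(d) else i}": dc.summarize_dmrs(d)
        for i, d in enumerate(dmr_sets)
    }
    manifest["summary"]["n_merged_dmrs"] = int(len(merged))

    # -- annotation + enrichment -------------------------------------------
    partition = ann.build_partition(
        genome.genes, genome.chrom_sizes, config.promoter_flank,
        cgis=genome.cgis, repeats=genome.repeats, hdrs=genome.hdrs,
    )
    enrich_rows = []
    for dmrs in dmr_sets:
        if not len(dmrs):
            continue
        comparison = dmrs["comparison"].iloc[0]
        shuffles = enr.shuffle_intervals(
            dmrs, genome.chrom_sizes, n_iter=n_shuffle, seed=config.seed
        )
        for feat in ("promoter", "gene_body", "intergenic", "promoter_cgi",
                     "orphan_cgi", "repeat"):
            res = enr.observed_expected(
                dmrs, partition.feature(feat), genome.chrom_sizes,
                shuffles=shuffles, feature_name=feat,
            )
            row = res.to_dict()
            row["comparison"] = comparison
            enrich_rows.append(row)
    enrich_df = pd.DataFrame(enrich_rows)
    out["enrichment"] = os.path.join(out_dir, "enrichment.tsv")
    enrich_df.to_csv(out["enrichment"], sep="\t", index=False)

    pooled = pd.concat(dmr_sets, ignore_index=True) if dmr_sets else merged
    assignments = ann.assign_dmrs_to_genes(
        pooled, genome.genes, genome.chrom_sizes, config.promoter_flank
    )
    out["dmr_gene_assignments"] = os.path.join(out_dir, "dmr_gene_assignments.tsv")
    assignments.to_csv(out["dmr_gene_assignments"], sep="\t", index=False)

    if len(merged) and len(genome.hdrs):
        dist = ann.distance_to_nearest(merged, genome.hdrs)
        manifest["summary"]["median_dmr_hdr_distance"] = float(
            np.median(dist[dist >= 0])
        ) if (dist >= 0).any() else None

    # -- expression ---------------------------------------------------------
    expr = study["expression"]
    deg_calls = ei.call_degs_all_pairs(expr)
    out["degs"] = os.path.join(out_dir, "degs.tsv")
    deg_calls.to_csv(out["degs"], sep="\t", index=False)
    manifest["summary"]["n_degs"] = int(
        deg_calls.loc[deg_calls["passes"], "gene_id"].nunique()
    )
    proms = ann.define_promoters(genome.genes, genome.chrom_sizes,
                                 config.promoter_flank)
    try:
        rho, rho_p = ei.promoter_meth_expr_correlation(wild, expr, proms)
        manifest["summary"]["promoter_meth_expr_rho"] = rho
        manifest["summary"]["promoter_meth_expr_p"] = rho_p
    except ValueError:
        manifest["summary"]["promoter_meth_expr_rho"] = None
    cross = ei.deg_dmr_crosstab(deg_calls, assignments)
    if cross["n_promoter_dmr_genes"] and cross["n_deg"]:
        rf, hp = enr.hypergeom_overlap(
            cross["n_universe"], cross["n_deg"],
            cross["n_promoter_dmr_genes"], cross["n_overlap"],
        )
        cross["representation_factor"] = rf
        cross["hypergeom_p"] = hp
    manifest["summary"]["deg_dmr_crosstab"] = cross

    # -- inheritance --------------------------------------------------------
    cg = mio.filter_coverage(study["common_garden"])
    calls = inh.classify_fixed_reset(merged, cg)
    out["inheritance"] = os.path.join(out_dir, "inheritance.tsv")
    calls.to_csv(out["inheritance"], sep="\t", index=False)
    testable = calls[calls["label"].isin(["fixed", "reset"])]
    if len(testable):
        fr_fixed, fr_reset = inh.inheritance_proportions(calls)
        summary = {"fraction_fixed": fr_fixed, "fraction_reset": fr_reset,
                   "n_testable": int(len(testable))}
        lengths = testable["end"] - testable["start"]
        fixed_l = lengths[testable["label"] == "fixed"]
        reset_l = lengths[testable["label"] == "reset"]
        if len(fixed_l) and len(reset_l):
            summary["length_comparison"] = inh.compare_lengths(
                fixed_l, reset_l, seed=config.seed
            )
        manifest["summary"]["inheritance"] = summary

    # -- cohort statistics --------------------------------------------------
    try:
        pca = ps.pca_methylome(wild)
        out["pca_scores"] = os.path.join(out_dir, "pca_scores.tsv")
        pca.scores.to_csv(out["pca_scores"], sep="\t")
        manifest["summary"]["pca_variance_explained"] = [
            float(v) for v in pca.variance_explained[:3]
        ]
    except ValueError:
        pass
    if len(merged):
        cpm = ps.cross_platform_matrix(wild, merged)
        out["dmr_methylation_matrix"] = os.path.join(out_dir, "dmr_methylation.tsv")
        cpm.to_csv(out["dmr_methylation_matrix"], sep="\t")
        usable = cpm.loc[:, cpm.notna().all(axis=0)]
        if usable.shape[1] >= 2:
            clust = ps.correlation_cluster(usable.T)
            out["dendrogram"] = os.path.join(out_dir, "samples.nwk")
            with open(out["dendrogram"], "w") as fh:
                fh.write(clust["newick"] + "\n")

    out_path = os.path.join(out_dir, "manifest.json")
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    manifest["outputs"]["manifest"] = out_path
    return manifest
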