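"""Genomic annotation: feature partition, DMR localisation and gene assignment.

The genome is partitioned into three mutually exclusive classes that jointly
cover every base pair: promoter (TSS +/- 1 kbp, strand-aware), gene body
(exons+introns minus the first 1 kbp downstream of the TSS) and intergenic
(everything else).  Where promoters and gene bodies of overlapping genes
collide, promoter wins.  CpG islands, transposon repeats and high-divergence
regions (HDRs) are overlays, not part of the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene models, CpG sites and feature overlays."""

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame            # gene_id, chrom, start, end, strand
    cpg_pos: dict[str, np.ndarray]  # sorted site positions per chromosome
    cgis: pd.DataFrame             # chrom, start, end, kind, cgi_id, gene_id
    repeats: pd.DataFrame          # chrom, start, end
    hdrs: pd.DataFrame             # chrom, start, end

    @property
    def n_cpg(self) -> int:
        return int(sum(len(p) for p in self.cpg_pos.values()))

    def cpg_site_frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"chrom": c, "pos": p}) for c, p in self.cpg_pos.items()
        ]
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["chrom", "pos"]
        )

    def write_bed_files(self, out_dir) -> dict[str, str]:
        """Write genes (BED6), CGIs, repeats and HDRs as BED files."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        genes = self.genes.copy()
        genes["score"] = 0
        bed6 = genes[["chrom", "start", "end", "gene_id", "score", "strand"]]
        paths["genes"] = os.path.join(out_dir, "genes.bed")
        bed6.to_csv(paths["genes"], sep="\t", header=False, index=False)
        for name, df in (
            ("cgis", self.cgis), ("repeats", self.repeats), ("hdrs", self.hdrs)
        ):
            paths[name] = os.path.join(out_dir, f"{name}.bed")
            cols = ["chrom", "start", "end"]
            if "cgi_id" in df.columns:
                cols = cols + ["cgi_id"]
            df[cols].to_csv(paths[name], sep="\t", header=False, index=False)
        sizes = pd.DataFrame(
            {"chrom": list(self.chrom_sizes), "size": list(self.chrom_sizes.values())}
        )
        paths["chrom_sizes"] = os.path.join(out_dir, "chrom.sizes")
        sizes.to_csv(paths["chrom_sizes"], sep="\t", header=False, index=False)
        return paths


def read_gene_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 6:
        raise ValueError("gene BED must be BED6 (strand required)")
    df = df.iloc[:, [0, 1, 2, 3, 4, 5]]
    df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
    return df[["gene_id", "chrom", "start", "end", "strand"]]


# ---------------------------------------------------------------------------
# TSS / promoters / gene bodies


def gene_tss(genes: pd.DataFrame) -> np.ndarray:
    """Strand-aware TSS coordinate (start for +, end for -)."""
    plus = genes["strand"].to_numpy() == "+"
    return np.where(plus, genes["start"].to_numpy(), genes["end"].to_numpy())


def gene_tes(genes: pd.DataFrame) -> np.ndarray:
    plus = genes["strand"].to_numpy() == "+"
    return np.where(plus, genes["end"].to_numpy(), genes["start"].to_numpy())


def define_promoters(genes: pd.DataFrame, chrom_sizes: dict[str, int],
                     flank: int = 1000) -> pd.DataFrame:
    """Per-gene promoter [TSS - flank, TSS + flank), clipped to the chromosome."""
    tss = gene_tss(genes)
    sizes = genes["chrom"].map(chrom_sizes).to_numpy()
    start = np.clip(tss - flank, 0, sizes)
    end = np.clip(tss + flank, 0, sizes)
    return pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "gene_id": genes["gene_id"].to_numpy(),
        }
    )


def define_gene_bodies(genes: pd.DataFrame, flank: int = 1000) -> pd.DataFrame:
    """Per-gene body: the gene minus the first ``flank`` bp downstream of the TSS.

    Genes of length <= ``flank`` yield empty bodies (dropped).
    """
    plus = genes["strand"].to_numpy() == "+"
    start = np.where(plus, genes["start"].to_numpy() + flank, genes["start"].to_numpy())
    end = np.where(plus, genes["end"].to_numpy(), genes["end"].to_numpy() - flank)
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "gene_id": genes["gene_id"].to_numpy(),
        }
    )
    return out[out["end"] > out["start"]].reset_index(drop=True)


@dataclass
class FeaturePartition:
    """Exclusive promoter/gene-body/intergenic tracks plus overlays."""

    promoter: pd.DataFrame
    gene_body: pd.DataFrame
    intergenic: pd.DataFrame
    promoter_cgi: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=iv.BED_COLUMNS))
    orphan_cgi: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=iv.BED_COLUMNS))
    repeat: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=iv.BED_COLUMNS))
    hdr: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=iv.BED_COLUMNS))

    EXCLUSIVE = ("promoter", "gene_body", "intergenic")

    def feature(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def build_partition(genes: pd.DataFrame, chrom_sizes: dict[str, int],
                    flank: int = 1000, cgis: pd.DataFrame | None = None,
                    repeats: pd.DataFrame | None = None,
                    hdrs: pd.DataFrame | None = None) -> FeaturePartition:
    """Build the exclusive partition, with promoter > gene body > intergenic."""
    genome = pd.DataFrame(
        {
            "chrom": list(chrom_sizes),
            "start": 0,
            "end": list(chrom_sizes.values()),
        }
    )
    prom = iv.merge_by_chrom(define_promoters(genes, chrom_sizes, flank))
    body_raw = iv.merge_by_chrom(define_gene_bodies(genes, flank))
    body = iv.subtract_by_chrom(body_raw, prom)
    inter = iv.subtract_by_chrom(
        iv.subtract_by_chrom(genome, prom), body
    )
    empty = pd.DataFrame(columns=iv.BED_COLUMNS)
    prom_cgi, orphan_cgi = empty, empty
    if cgis is not None and len(cgis):
        in_prom = iv.overlaps_any_by_chrom(cgis, prom)
        prom_cgi = cgis.loc[in_prom, iv.BED_COLUMNS].reset_index(drop=True)
        orphan_cgi = cgis.loc[~in_prom, iv.BED_COLUMNS].reset_index(drop=True)
    return FeaturePartition(
        promoter=prom,
        gene_body=body,
        intergenic=inter,
        promoter_cgi=prom_cgi,
        orphan_cgi=orphan_cgi,
        repeat=repeats[iv.BED_COLUMNS].copy() if repeats is not None and len(repeats) else empty,
        hdr=hdrs[iv.BED_COLUMNS].copy() if hdrs is not None and len(hdrs) else empty,
    )


# ---------------------------------------------------------------------------
# DMR localisation


def localize_dmrs(dmrs: pd.DataFrame, partition: FeaturePartition) -> pd.DataFrame:
    """Per-DMR feature localisation.

    The exclusive class (promoter/gene_body/intergenic) is assigned by the
    majority-base-pair rule with ties broken in the order promoter >
    gene_body > intergenic.  Overlay columns flag >= 1 bp overlap.
    """
    dmrs = dmrs.reset_index(drop=True)
    out = dmrs[iv.BED_COLUMNS].copy()
    ov = {}
    for name in FeaturePartition.EXCLUSIVE:
        ov[name] = iv.overlap_length_by_chrom(out, partition.feature(name))
    stacked = np.vstack([ov[n] for n in FeaturePartition.EXCLUSIVE])
    best = np.argmax(stacked, axis=0)  # argmax takes the first on ties
    out["feature_class"] = [FeaturePartition.EXCLUSIVE[i] for i in best]
    for name in ("promoter_cgi", "orphan_cgi", "repeat", "hdr"):
        out[f"in_{name}"] = iv.overlaps_any_by_chrom(out, partition.feature(name))
    out["in_cgi"] = out["in_promoter_cgi"] | out["in_orphan_cgi"]
    for name in FeaturePartition.EXCLUSIVE:
        out[f"bp_{name}"] = ov[name]
        out[f"touches_{name}"] = ov[name] > 0
    return out


def localization_counts(localized: pd.DataFrame) -> dict[str, int]:
    """Overlap tallies per feature class (>=1 bp rule for overlays)."""
    counts = {
        name: int(localized[f"touches_{name}"].sum())
        for name in FeaturePartition.EXCLUSIVE
    }
    for name in ("promoter_cgi", "orphan_cgi", "cgi", "repeat", "hdr"):
        counts[name] = int(localized[f"in_{name}"].sum())
    return counts


# ---------------------------------------------------------------------------
# DMR -> gene assignment


def assign_dmrs_to_genes(dmrs: pd.DataFrame, genes: pd.DataFrame,
                         chrom_sizes: dict[str, int], flank: int = 1000,
                         min_overlap_frac: float = 0.5,
                         intergenic_range: tuple[int, int] = (1000, 5000),
                         ) -> pd.DataFrame:
    """Assign DMRs to genes.

    A DMR maps to a gene's promoter (or body) when >= ``min_overlap_frac`` of
    the DMR's length overlaps that per-gene feature; multiple genes may
    qualify.  A DMR with no such assignment whose nearest-gene gap lies in
    ``intergenic_range`` (inclusive) maps to that nearest gene as
    "intergenic".  Returns one row per (dmr, gene, class).
    """
    dmrs = dmrs.reset_index(drop=True)
    promoters = define_promoters(genes, chrom_sizes, flank)
    bodies = define_gene_bodies(genes, flank)
    rows = []
    assigned = np.zeros(len(dmrs), dtype=bool)

    for feature, klass in ((promoters, "promoter"), (bodies, "gene_body")):
        for chrom, dsub in dmrs.groupby("chrom", sort=False):
            fsub = feature[feature["chrom"] == chrom]
            if fsub.empty or dsub.empty:
                continue
            ds = dsub["start"].to_numpy()[:, None]
            de = dsub["end"].to_numpy()[:, None]
            fs = fsub["start"].to_numpy()[None, :]
            fe = fsub["end"].to_numpy()[None, :]
            ov = np.clip(np.minimum(de, fe) - np.maximum(ds, fs), 0, None)
            frac_ok = ov >= min_overlap_frac * (de - ds)
            frac_ok &= ov > 0
            di, fi = np.nonzero(frac_ok)
            for a, b in zip(di, fi):
                idx = dsub.index[a]
                rows.append(
                    {
                        "dmr_index": idx,
                        "gene_id": fsub["gene_id"].iloc[b],
                        "assignment": klass,
                        "overlap_bp": int(ov[a, b]),
                        "distance": 0,
                    }
                )
                assigned[idx] = True

    lo, hi = intergenic_range
    for chrom, dsub in dmrs.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        un = dsub.index[~assigned[dsub.index]]
        if len(un) == 0:
            continue
        ds = dmrs.loc[un, "start"].to_numpy()[:, None]
        de = dmrs.loc[un, "end"].to_numpy()[:, None]
        gs = gsub["start"].to_numpy()[None, :]
        ge = gsub["end"].to_numpy()[None, :]
        gap = np.maximum(0, np.maximum(gs - de, ds - ge))
        nearest = np.argmin(gap, axis=1)
        best = gap[np.arange(len(un)), nearest]
        for k, idx in enumerate(un):
            if lo <= best[k] <= hi:
                rows.append(
                    {
                        "dmr_index": idx,
                        "gene_id": gsub["gene_id"].iloc[nearest[k]],
                        "assignment": "intergenic",
                        "overlap_bp": 0,
                        "distance": int(best[k]),
                    }
                )

    out = pd.DataFrame(rows, columns=["dmr_index", "gene_id", "assignment",
                                      "overlap_bp", "distance"])
    return out.sort_values(["dmr_index", "gene_id"], ignore_index=True)


def distance_to_nearest(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Per-query min gap to same-chromosome subjects; -1 where none exists.

    Pure gap convention: touching or overlapping intervals are at distance 0.
    """
    return iv.gap_distance_by_chrom(query.reset_index(drop=True), subject)


def audit_partition(partition: FeaturePartition, chrom_sizes: dict[str, int]) -> bool:
    """Check disjointness and exhaustiveness by per-bp occupancy."""
    for chrom, size in chrom_sizes.items():
        occ = np.zeros(size, dtype=np.int8)
        for name in FeaturePartition.EXCLUSIVE:
            f = partition.feature(name)
            for s, e in f[f["chrom"] == chrom][["start", "end"]].itertuples(index=False):
                occ[s:e] += 1
        if not np.all(occ == 1):
            return False
    return True
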