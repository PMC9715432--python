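"""Synthetic bisulfite-count datasets with planted ground truth.

Generates an internally consistent study: a genome with strand-assigned
gene models, CpG sites (homogeneous Poisson background with denser CpG
islands), transposon repeats and high-divergence regions; per-CpG
methylation count cohorts for two or three populations with planted
inter-population DMRs; a TPM expression matrix with planted DEGs coupled
negatively to promoter methylation; and a common-garden generation in which
a configurable fraction of the planted DMRs is retained (fixed) while the
rest revert to baseline (reset).

Planted DMRs are anchored at CpG islands: empirically, population-scale
methylome divergence concentrates at CpG-dense regulatory elements, and the
anchoring reproduces that local density regime (tens of CG sites per few
hundred bp) around the planted effect.

Randomness: one global seed; each stage draws from its own substream
(``default_rng([seed, STAGE])``) so stages are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, define_promoters
from .config import ConfigError, SimulationConfig
from .expression_integration import ExpressionMatrix
from .methylome_io import MethylomeMatrix

# rng substream tags
_GENOME, _COHORT, _EXPRESSION, _COMMON_GARDEN, _LABELS = 11, 22, 33, 44, 55

PROP_CLIP = (0.01, 0.99)  # keeps binomial draws non-degenerate / Wald SEs finite


@dataclass
class PlantedTruth:
    """Ground truth of a simulated study.

    ``dmrs``: one row per planted DMR (interval, focal population,
    direction, effect, site span, host gene when promoter-anchored,
    inheritance label once the common-garden cohort exists).
    ``degs``: one row per planted DEG.
    """

    dmrs: pd.DataFrame
    degs: pd.DataFrame = field(default_factory=pd.DataFrame)
    # in-memory only: generating proportions, needed by downstream stages
    site_props: np.ndarray | None = None        # (n_sites,) baseline
    pop_props: np.ndarray | None = None         # (n_sites, n_pops) wild
    site_frame: pd.DataFrame | None = None      # chrom/pos per site

    @property
    def inheritance_labels(self) -> pd.Series:
        if "inheritance" not in self.dmrs.columns:
            raise ValueError("common-garden cohort not simulated yet")
        return self.dmrs["inheritance"]

    def to_json(self, path) -> None:
        payload = {
            "dmrs": self.dmrs.drop(
                columns=[c for c in ("site_start", "site_end") if c in self.dmrs],
            ).to_dict(orient="records"),
            "degs": self.degs.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), tag])


# ---------------------------------------------------------------------------
# Genome


def generate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Simulate chromosome sizes, gene models, CpG map, CGIs, repeats, HDRs."""
    config.validate()
    rng = _rng(config, _GENOME)
    chrom_sizes = {c: int(config.chrom_length) for c in config.chrom_names}
    genes_parts, cgi_parts, rep_parts, hdr_parts = [], [], [], []
    cpg_pos: dict[str, np.ndarray] = {}

    # distribute genes over chromosomes round-robin
    per_chrom = np.zeros(config.n_chromosomes, dtype=int)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    per_chrom += config.n_genes // config.n_chromosomes

    gene_counter = 0
    cgi_counter = 0
    for ci, chrom in enumerate(config.chrom_names):
        L = chrom_sizes[chrom]
        n_g = int(per_chrom[ci])
        glo, ghi = config.gene_length_range
        lengths = rng.integers(glo, ghi + 1, size=n_g) if n_g else np.array([], int)
        slack = L - int(lengths.sum()) - (n_g + 1) * config.min_gene_gap
        if slack < 0:
            raise ConfigError(
                f"{chrom} ({L} bp) too short for {n_g} genes of "
                f"{glo}-{ghi} bp with {config.min_gene_gap} bp gaps"
            )
        extra = rng.multinomial(slack, np.full(n_g + 1, 1.0 / (n_g + 1))) if n_g else []
        starts = []
        cursor = 0
        for i in range(n_g):
            cursor += config.min_gene_gap + int(extra[i])
            starts.append(cursor)
            cursor += int(lengths[i])
        strands = rng.choice(["+", "-"], size=n_g)
        ids = [f"g{gene_counter + i:05d}" for i in range(n_g)]
        gene_counter += n_g
        gdf = pd.DataFrame(
            {
                "gene_id": ids,
                "chrom": chrom,
                "start": np.asarray(starts, dtype=np.int64),
                "end": np.asarray(starts, dtype=np.int64) + lengths,
                "strand": strands,
            }
        )
        genes_parts.append(gdf)

        # CpG islands: a fraction of promoters host one (centred on the TSS),
        # plus orphan islands placed away from promoters
        proms = define_promoters(gdf, chrom_sizes, config.promoter_flank)
        n_prom_cgi = int(round(config.promoter_cgi_fraction * n_g))
        host = rng.choice(n_g, size=n_prom_cgi, replace=False) if n_prom_cgi else []
        clo, chi_ = config.cgi_length_range
        cgi_rows = []
        for gi in host:
            length = int(rng.integers(clo, chi_ + 1))
            tss = gdf["start"].iloc[gi] if gdf["strand"].iloc[gi] == "+" else gdf["end"].iloc[gi]
            s = int(np.clip(tss - length // 2, 0, L - length))
            cgi_rows.append((s, s + length, "promoter", gdf["gene_id"].iloc[gi]))
        prom_s = proms["start"].to_numpy()
        prom_e = proms["end"].to_numpy()
        placed = 0
        attempts = 0
        while placed < config.n_orphan_cgis and attempts < 100 * max(config.n_orphan_cgis, 1):
            attempts += 1
            length = int(rng.integers(clo, chi_ + 1))
            s = int(rng.integers(0, L - length + 1))
            if np.any((prom_s < s + length) & (prom_e > s)):
                continue
            if any((r[0] < s + length) and (r[1] > s) for r in cgi_rows):
                continue
            cgi_rows.append((s, s + length, "orphan", None))
            placed += 1
        for s, e, kind, gid in cgi_rows:
            cgi_parts.append(
                {
                    "chrom": chrom, "start": s, "end": e, "kind": kind,
                    "cgi_id": f"cgi{cgi_counter:05d}", "gene_id": gid,
                }
            )
            cgi_counter += 1

        # repeats and HDRs: random intervals (overlaps permitted for repeats)
        rlo, rhi = config.repeat_length_range
        for _ in range(config.n_repeats):
            length = int(rng.integers(rlo, rhi + 1))
            s = int(rng.integers(0, max(L - length, 0) + 1))
            rep_parts.append({"chrom": chrom, "start": s, "end": s + length})
        hlo, hhi = config.hdr_length_range
        for _ in range(config.n_hdrs):
            length = int(rng.integers(hlo, min(hhi, L) + 1))
            s = int(rng.integers(0, max(L - length, 0) + 1))
            hdr_parts.append({"chrom": chrom, "start": s, "end": s + length})

        # CpG sites: homogeneous Poisson background + extra density in CGIs
        lam = config.cpg_density / 1000.0
        n_bg = rng.poisson(lam * L)
        pos = rng.integers(0, L, size=n_bg)
        extra_pos = []
        for s, e, _, _ in cgi_rows:
            n_x = rng.poisson((config.cgi_density_multiplier - 1.0) * lam * (e - s))
            if n_x:
                extra_pos.append(rng.integers(s, e, size=n_x))
        if extra_pos:
            pos = np.concatenate([pos] + extra_pos)
        cpg_pos[chrom] = np.unique(pos).astype(np.int64)

    def _frame(parts, cols):
        return (pd.DataFrame(parts) if parts else pd.DataFrame(columns=cols))

    return GenomeAnnotation(
        chrom_sizes=chrom_sizes,
        genes=(pd.concat(genes_parts, ignore_index=True) if genes_parts
               else pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])),
        cpg_pos=cpg_pos,
        cgis=_frame(cgi_parts, ["chrom", "start", "end", "kind", "cgi_id", "gene_id"]),
        repeats=_frame(rep_parts, ["chrom", "start", "end"]),
        hdrs=_frame(hdr_parts, ["chrom", "start", "end"]),
    )


# ---------------------------------------------------------------------------
# Compartments and baseline proportions


def site_compartments(genome: GenomeAnnotation,
                      config: SimulationConfig) -> np.ndarray:
    """Per-CpG compartment label, precedence promoter_cgi > orphan_cgi >
    promoter > gene_body > repeat > intergenic."""
    from . import intervals as iv
    from .annotation import define_gene_bodies

    frames = {
        "promoter": define_promoters(genome.genes, genome.chrom_sizes,
                                     config.promoter_flank),
        "gene_body": define_gene_bodies(genome.genes, config.promoter_flank),
        "repeat": genome.repeats,
    }
    if len(genome.cgis):
        frames["promoter_cgi"] = genome.cgis[genome.cgis["kind"] == "promoter"]
        frames["orphan_cgi"] = genome.cgis[genome.cgis["kind"] == "orphan"]
    order = ["promoter_cgi", "orphan_cgi", "promoter", "gene_body", "repeat"]
    labels = []
    for chrom, pos in genome.cpg_pos.items():
        lab = np.full(len(pos), "intergenic", dtype=object)
        for name in reversed(order):
            f = frames.get(name)
            if f is None or len(f) == 0:
                continue
            fsub = f[f["chrom"] == chrom]
            if fsub.empty:
                continue
            hit = iv.overlaps_any(pos, pos + 1, fsub["start"].to_numpy(),
                                  fsub["end"].to_numpy())
            lab[hit] = name
        labels.append(lab)
    return np.concatenate(labels) if labels else np.array([], dtype=object)


def _baseline_props(genome, config, rng) -> tuple[np.ndarray, pd.DataFrame]:
    comp = site_compartments(genome, config)
    base = np.array(
        [config.baseline_methylation.get(c, 0.75) for c in comp], dtype=float
    )
    c = config.site_concentration
    props = rng.beta(np.maximum(base * c, 1e-6), np.maximum((1 - base) * c, 1e-6))
    props = np.clip(props, *PROP_CLIP)
    sites = genome.cpg_site_frame()
    return props, sites


# ---------------------------------------------------------------------------
# Planted DMRs


def _plant_dmrs(genome, config, rng, site_props, sites) -> pd.DataFrame:
    """Choose CGI-anchored intervals and record the planted effects."""
    if config.n_planted_dmrs == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "focal", "direction", "effect",
                     "n_cpg", "gene_id", "cgi_id", "site_start", "site_end"]
        )
    min_sites, max_sites = config.dmr_sites_range
    lo_len, hi_len = config.dmr_length_range
    # global site offsets per chromosome
    offsets, off = {}, 0
    for chrom, pos in genome.cpg_pos.items():
        offsets[chrom] = off
        off += len(pos)
    cgis = genome.cgis.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    pops = config.population_names
    rows = []
    for r in cgis.itertuples():
        if len(rows) >= config.n_planted_dmrs:
            break
        pos = genome.cpg_pos[r.chrom]
        lo = np.searchsorted(pos, r.start)
        hi = np.searchsorted(pos, r.end)
        if hi - lo < min_sites:
            continue
        cgi_len = r.end - r.start
        target = int(rng.integers(lo_len, hi_len + 1))
        target = min(target, cgi_len)
        s = int(rng.integers(r.start, r.end - target + 1))
        a = np.searchsorted(pos, s)
        b = np.searchsorted(pos, s + target)
        if b - a < min_sites:          # fall back to the whole island
            a, b = lo, hi
        if b - a > max_sites:          # trim to a random contiguous run
            a = a + int(rng.integers(0, (b - a) - max_sites + 1))
            b = a + max_sites
        start = int(pos[a])
        end = int(pos[b - 1]) + 2      # CpG dinucleotide occupies 2 bp
        focal = pops[int(rng.integers(1, len(pops)))]
        local = float(site_props[offsets[r.chrom] + a: offsets[r.chrom] + b].mean())
        direction = "gain" if local + config.dmr_effect <= PROP_CLIP[1] else "loss"
        rows.append(
            {
                "chrom": r.chrom, "start": start, "end": end,
                "focal": focal, "direction": direction,
                "effect": float(config.dmr_effect),
                "n_cpg": int(b - a),
                "gene_id": r.gene_id if r.kind == "promoter" else None,
                "cgi_id": r.cgi_id,
                "site_start": int(offsets[r.chrom] + a),
                "site_end": int(offsets[r.chrom] + b),
            }
        )
    if len(rows) < config.n_planted_dmrs:
        raise ConfigError(
            f"only {len(rows)} CpG islands can host the requested "
            f"{config.n_planted_dmrs} planted DMRs; add genes/orphan CGIs"
        )
    return pd.DataFrame(rows)


def _apply_dmr_shifts(pop_props: np.ndarray, dmr_rows: pd.DataFrame,
                      pop_index: dict[str, int]) -> None:
    for r in dmr_rows.itertuples():
        sl = slice(r.site_start, r.site_end)
        sign = 1.0 if r.direction == "gain" else -1.0
        pop_props[sl, pop_index[r.focal]] = np.clip(
            pop_props[sl, pop_index[r.focal]] + sign * r.effect, *PROP_CLIP
        )


def _draw_counts(rng, props, n_samples_per_pop, pops, coverage_mean,
                 coverage_dispersion, sample_tag) -> tuple[np.ndarray, np.ndarray, list, dict]:
    n_sites, _ = props.shape
    samples, pop_of = [], {}
    meth_cols, tot_cols = [], []
    r = coverage_dispersion
    p_nb = r / (r + coverage_mean)
    for pi, pop in enumerate(pops):
        for si in range(n_samples_per_pop):
            name = f"{pop}_{sample_tag}{si + 1}"
            samples.append(name)
            pop_of[name] = pop
            cov = rng.negative_binomial(r, p_nb, size=n_sites)
            meth = rng.binomial(cov, props[:, pi])
            meth_cols.append(meth)
            tot_cols.append(cov)
    return (np.column_stack(meth_cols), np.column_stack(tot_cols), samples, pop_of)


def simulate_methylation_cohort(genome: GenomeAnnotation,
                                config: SimulationConfig,
                                ) -> tuple[MethylomeMatrix, PlantedTruth]:
    """Simulate the wild cohort: NB coverage, binomial methylated counts.

    Inside planted DMRs the focal population's generating proportion is
    shifted by +/- ``dmr_effect`` (clipped); the returned truth records all
    planted intervals and carries the generating proportions for the
    downstream expression and common-garden stages.
    """
    config.validate()
    rng = _rng(config, _COHORT)
    site_props, sites = _baseline_props(genome, config, rng)
    pops = config.population_names
    pop_index = {p: i for i, p in enumerate(pops)}
    pop_props = np.tile(site_props[:, None], (1, len(pops)))
    dmr_rows = _plant_dmrs(genome, config, rng, site_props, sites)
    _apply_dmr_shifts(pop_props, dmr_rows, pop_index)
    meth, total, samples, pop_of = _draw_counts(
        rng, pop_props, config.samples_per_population, pops,
        config.coverage_mean, config.coverage_dispersion, "w",
    )
    matrix = MethylomeMatrix(sites, meth, total, samples, pop_of)
    truth = PlantedTruth(dmrs=dmr_rows, site_props=site_props,
                         pop_props=pop_props, site_frame=sites)
    return matrix, truth


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(genome: GenomeAnnotation, truth: PlantedTruth,
                        config: SimulationConfig) -> ExpressionMatrix:
    """Log-normal TPM with planted DEGs and negative methylation coupling.

    Gene-level mean log2 TPM decreases with mean promoter methylation of the
    generating proportions (slope ``meth_expression_slope``), making the
    cohort-wide Spearman correlation between promoter methylation and
    expression negative by construction.  A fraction ``deg_dmr_coupling`` of
    planted DEGs are genes hosting a planted promoter DMR; their expression
    shift in the focal population opposes the methylation shift.
    """
    config.validate()
    if truth.pop_props is None:
        raise ValueError("simulate the methylation cohort first")
    rng = _rng(config, _EXPRESSION)
    genes = genome.genes.reset_index(drop=True)
    n_genes = len(genes)
    if n_genes == 0:
        raise ConfigError("expression simulation needs >= 1 gene")
    pops = config.population_names
    pop_index = {p: i for i, p in enumerate(pops)}

    # per-gene, per-population mean promoter methylation of the generating process
    proms = define_promoters(genes, genome.chrom_sizes, config.promoter_flank)
    offsets, off = {}, 0
    for chrom, pos in genome.cpg_pos.items():
        offsets[chrom] = off
        off += len(pos)
    prom_meth = np.full((n_genes, len(pops)), 0.55)
    for i, r in enumerate(proms.itertuples()):
        pos = genome.cpg_pos[r.chrom]
        lo = np.searchsorted(pos, r.start)
        hi = np.searchsorted(pos, r.end)
        if hi > lo:
            prom_meth[i] = truth.pop_props[offsets[r.chrom] + lo:
                                           offsets[r.chrom] + hi].mean(axis=0)

    base = rng.normal(config.expression_base_mean, config.expression_base_sd,
                      size=n_genes)
    base = base - config.meth_expression_slope * (prom_meth.mean(axis=1) - 0.5)
    mu = np.tile(base[:, None], (1, len(pops)))

    # planted DEGs
    n_deg = config.n_planted_degs
    n_coupled = int(round(config.deg_dmr_coupling * n_deg))
    prom_dmrs = truth.dmrs[truth.dmrs["gene_id"].notna()] if len(truth.dmrs) else (
        truth.dmrs
    )
    gene_row = {g: i for i, g in enumerate(genes["gene_id"])}
    dmr_genes = [g for g in prom_dmrs["gene_id"] if g in gene_row] if len(prom_dmrs) else []
    if n_coupled > len(dmr_genes):
        raise ConfigError(
            f"requested {n_coupled} promoter-DMR-coupled DEGs but only "
            f"{len(dmr_genes)} genes host a planted promoter DMR"
        )
    deg_rows = []
    chosen = set()
    if n_coupled:
        picked = rng.choice(len(dmr_genes), size=n_coupled, replace=False)
        for k in picked:
            g = dmr_genes[k]
            src = prom_dmrs[prom_dmrs["gene_id"] == g].iloc[0]
            sign = -1.0 if src["direction"] == "gain" else 1.0
            gi = gene_row[g]
            base_hi = max(base[gi], np.log2(20.0))
            mu[gi, :] = base_hi
            mu[gi, pop_index[src["focal"]]] = base_hi + sign * config.deg_log2fc
            chosen.add(g)
            deg_rows.append({"gene_id": g, "focal": src["focal"],
                             "log2fc_sign": sign, "coupled": True})
    free = [g for g in genes["gene_id"]
            if g not in chosen and g not in set(dmr_genes)]
    n_free = n_deg - n_coupled
    if n_free > len(free):
        raise ConfigError("not enough genes for the requested uncoupled DEGs")
    if n_free:
        for k in rng.choice(len(free), size=n_free, replace=False):
            g = free[k]
            gi = gene_row[g]
            sign = float(rng.choice([-1.0, 1.0]))
            focal = pops[int(rng.integers(1, len(pops)))]
            base_hi = max(base[gi], np.log2(20.0))
            mu[gi, :] = base_hi
            mu[gi, pop_index[focal]] = base_hi + sign * config.deg_log2fc
            chosen.add(g)
            deg_rows.append({"gene_id": g, "focal": focal,
                             "log2fc_sign": sign, "coupled": False})

    samples, pop_of = [], {}
    cols = {}
    for pop in pops:
        for si in range(config.expression_samples_per_population):
            name = f"{pop}_rna{si + 1}"
            samples.append(name)
            pop_of[name] = pop
            noise = rng.normal(0.0, config.expression_noise_sd, size=n_genes)
            cols[name] = np.power(2.0, mu[:, pop_index[pop]] + noise)
    tpm = pd.DataFrame(cols, index=genes["gene_id"])
    truth.degs = pd.DataFrame(
        deg_rows, columns=["gene_id", "focal", "log2fc_sign", "coupled"]
    )
    return ExpressionMatrix(tpm=tpm, populations=pop_of)


# ---------------------------------------------------------------------------
# Common garden


def simulate_common_garden(genome: GenomeAnnotation, truth: PlantedTruth,
                           config: SimulationConfig) -> MethylomeMatrix:
    """Simulate the first common-garden generation (G1).

    Planted DMRs are labelled fixed with probability ``fraction_fixed``
    (recorded in ``truth.dmrs["inheritance"]``); fixed DMRs keep their
    focal-population shift, reset DMRs revert every population to the
    baseline proportion.
    """
    config.validate()
    if truth.site_props is None:
        raise ValueError("simulate the wild cohort first")
    label_rng = _rng(config, _LABELS)
    n_dmr = len(truth.dmrs)
    fixed = label_rng.random(n_dmr) < config.fraction_fixed
    truth.dmrs = truth.dmrs.copy()
    truth.dmrs["inheritance"] = np.where(fixed, "fixed", "reset")

    pops = config.population_names
    pop_index = {p: i for i, p in enumerate(pops)}
    cg_props = np.tile(truth.site_props[:, None], (1, len(pops)))
    _apply_dmr_shifts(cg_props, truth.dmrs[fixed], pop_index)

    rng = _rng(config, _COMMON_GARDEN)
    meth, total, samples, pop_of = _draw_counts(
        rng, cg_props, config.cg_samples_per_population, pops,
        config.coverage_mean, config.coverage_dispersion, "cg",
    )
    return MethylomeMatrix(truth.site_frame.copy(), meth, total, samples, pop_of)


# ---------------------------------------------------------------------------
# Convenience: full simulated study


def simulate_study(config: SimulationConfig) -> dict:
    """Genome + wild cohort + expression + common garden, keyed by stage."""
    genome = generate_genome(config)
    wild, truth = simulate_methylation_cohort(genome, config)
    expr = simulate_expression(genome, truth, config)
    cg = simulate_common_garden(genome, truth, config)
    return {"genome": genome, "wild": wild, "truth": truth,
            "expression": expr, "common_garden": cg}
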