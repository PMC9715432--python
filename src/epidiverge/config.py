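"""Simulation configuration.

A single :class:`SimulationConfig` drives every stage of the synthetic data
generator: genome layout, bisulfite-count cohorts with planted differentially
methylated regions (DMRs), coupled expression with planted differentially
expressed genes (DEGs), and the common-garden generation in which a fraction
of the planted DMRs is inherited ("fixed") while the rest revert ("reset").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised when a simulation or analysis configuration is inconsistent."""


#: Default baseline mCG/CG levels per genomic compartment.  Fish methylomes
#: are globally hypermethylated with hypomethylated CpG islands, so gene
#: bodies sit high and promoter CGIs low.
DEFAULT_BASELINES: dict[str, float] = {
    "promoter_cgi": 0.10,
    "orphan_cgi": 0.15,
    "promoter": 0.55,
    "gene_body": 0.85,
    "intergenic": 0.75,
    "repeat": 0.85,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Counts are per chromosome where noted; lengths in bp; methylation values
    are proportions in [0, 1].
    """

    # genome layout
    n_chromosomes: int = 4
    chrom_length: int = 2_500_000
    cpg_density: float = 10.0           # background CpG sites per kbp
    cgi_density_multiplier: float = 5.0  # CpG density inside CpG islands
    n_genes: int = 300                   # total, spread over chromosomes
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    min_gene_gap: int = 4_000
    promoter_flank: int = 1_000
    promoter_cgi_fraction: float = 0.5   # fraction of promoters hosting a CGI
    n_orphan_cgis: int = 15              # per chromosome
    cgi_length_range: tuple[int, int] = (400, 1_500)
    n_repeats: int = 40                  # per chromosome (transposon intervals)
    repeat_length_range: tuple[int, int] = (200, 5_000)
    n_hdrs: int = 3                      # per chromosome (high-divergence regions)
    hdr_length_range: tuple[int, int] = (20_000, 100_000)

    # cohorts
    n_populations: int = 2
    samples_per_population: int = 3
    baseline_methylation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    site_concentration: float = 30.0     # beta concentration of site-level levels
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0     # negative-binomial size parameter

    # planted inter-population DMRs
    n_planted_dmrs: int = 150
    dmr_effect: float = 0.45
    dmr_length_range: tuple[int, int] = (50, 3_000)
    dmr_sites_range: tuple[int, int] = (4, 232)

    # planted DEGs and methylation-expression coupling
    n_planted_degs: int = 60
    deg_log2fc: float = 2.0
    deg_dmr_coupling: float = 0.43       # fraction of DEGs coupled to promoter DMRs
    expression_samples_per_population: int = 5
    expression_noise_sd: float = 0.4     # per-sample sd on log2 TPM
    expression_base_mean: float = 3.5    # mean of gene-level log2 TPM
    expression_base_sd: float = 2.5
    meth_expression_slope: float = 8.0   # log2 TPM decrease per unit promoter mCG/CG

    # common-garden generation
    fraction_fixed: float = 0.112
    cg_samples_per_population: int = 2

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        err = []
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            err.append("genome must have >=1 chromosome of positive length")
        if self.n_populations not in (2, 3):
            err.append("n_populations must be 2 or 3")
        for name in ("cpg_density", "coverage_mean", "coverage_dispersion",
                     "site_concentration"):
            if getattr(self, name) <= 0:
                err.append(f"{name} must be positive")
        for name in ("dmr_effect", "fraction_fixed", "deg_dmr_coupling",
                     "promoter_cgi_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                err.append(f"{name} must lie in [0, 1]")
        for name, v in self.baseline_methylation.items():
            if not 0.0 <= v <= 1.0:
                err.append(f"baseline_methylation[{name!r}] must lie in [0, 1]")
        for name in ("dmr_length_range", "dmr_sites_range", "gene_length_range",
                     "cgi_length_range", "repeat_length_range", "hdr_length_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                err.append(f"{name} must be an ordered nonnegative pair")
        for name in ("n_genes", "n_planted_dmrs", "n_planted_degs",
                     "samples_per_population", "cg_samples_per_population",
                     "expression_samples_per_population", "n_orphan_cgis",
                     "n_repeats", "n_hdrs"):
            if getattr(self, name) < 0:
                err.append(f"{name} must be >= 0")
        if err:
            raise ConfigError("; ".join(err))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- derived ------------------------------------------------------------
    @property
    def population_names(self) -> list[str]:
        if self.n_populations == 2:
            return ["littoral", "benthic"]
        return ["river", "littoral", "benthic"]

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]
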