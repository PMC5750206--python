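"""Simulation configuration for the synthetic diploid genome.

Defaults reproduce the study conditions of the genome being modelled: a compact
(~2 Mb here, scaled from 109 Mb) heterozygous genome with ~98.2% inter-haplotype
identity, one gene per ~4 kb, young LTR retrotransposons dated under a neutral
rate of mu = 1.3e-8 substitutions per bp per year, aggressive solo-LTR formation
(solo:intact around 4), and ~20 large haplotype-specific indels of 4.8–85 kb
that are LTR-rich (~58% of bases) and gene-poor (~9% of bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SizingError(ConfigError):
    """Requested features do not fit the requested sequence length."""


@dataclass(frozen=True)
class AgeDistribution:
    """Named age distribution for planted LTR elements (ages in years).

    ``kind`` is one of:

    * ``"exponential"`` — Exp(mean) truncated at ``max_age`` (young-skewed,
      the shape of an active, rapidly purged LTR population);
    * ``"uniform"`` — Uniform(min_age, max_age).
    """

    kind: str = "exponential"
    mean: float = 4.0e5
    min_age: float = 0.0
    max_age: float = 2.0e6

    def validate(self) -> None:
        if self.kind not in ("exponential", "uniform"):
            raise ConfigError(f"unknown age distribution kind {self.kind!r}")
        if self.max_age <= self.min_age:
            raise ConfigError("age distribution requires min_age < max_age")
        if self.kind == "exponential" and self.mean <= 0:
            raise ConfigError("exponential age distribution requires mean > 0")

    def sample(self, rng, n: int):
        import numpy as np

        if self.kind == "uniform":
            return rng.uniform(self.min_age, self.max_age, size=n)
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.exponential(self.mean, size=n - filled) + self.min_age
            keep = draw[draw <= self.max_age]
            out[filled : filled + keep.size] = keep
            filled += keep.size
        return out


#: Per-context mean methylation levels for each genomic compartment.
#: Gene bodies are essentially unmethylated (no gene-body methylation);
#: LTR bodies carry high CpG/CHG and low CHH methylation; levels ramp down
#: across 1 kb flanks toward a low genomic background.
DEFAULT_METHYLATION_PROFILE: dict[str, dict[str, float]] = {
    "gene_body": {"CpG": 0.01, "CHG": 0.01, "CHH": 0.01},
    "ltr_body": {"CpG": 0.85, "CHG": 0.75, "CHH": 0.10},
    "background": {"CpG": 0.05, "CHG": 0.04, "CHH": 0.02},
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic diploid genome generator.

    Fractions are in [0, 1]; lengths in bp; rates per bp; ages in years.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 1_000_000
    #: genes per bp (default one gene per 4.0 kb).
    gene_density: float = 1.0 / 4000.0
    #: substitutions per bp between the two haplotypes (98.2% identity).
    snp_rate: float = 0.018
    #: neutral substitution rate, per bp per year.
    mu: float = 1.3e-8
    #: number of LTR elements planted before solo-LTR formation.
    n_intact_ltr: int = 150
    ltr_age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    #: ages of elements planted inside haplotype-specific indels (younger:
    #: young elements are over-represented in haplotype-specific regions).
    indel_ltr_age_distribution: AgeDistribution = field(
        default_factory=lambda: AgeDistribution(kind="exponential", mean=4.0e4, max_age=1.0e5)
    )
    #: fraction of planted elements converted to solo LTRs.
    solo_fraction: float = 0.8
    n_planted_indels: int = 20
    indel_size_range: tuple[int, int] = (4_800, 85_000)
    #: target fraction of indel bp that is LTR retrotransposon.
    indel_ltr_fraction: float = 0.58
    #: target fraction of indel bp that is genic.
    indel_gene_fraction: float = 0.09
    methylation_profile: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_METHYLATION_PROFILE.items()}
    )
    #: mean sequencing coverage per cytosine (Poisson).
    coverage_mean: float = 10.0
    #: number of bisulfite replicates.
    n_replicates: int = 3
    #: fraction of indel-region genes with TPM below 0.5.
    indel_gene_silent_fraction: float = 0.74
    #: gene length range in codons (CDS = 3 * codons).
    gene_codon_range: tuple[int, int] = (150, 650)
    #: mean intergenic gap inside gene islands, bp.
    intergenic_mean: int = 1_100
    #: genes per gene island (mean).
    island_size: int = 8
    #: target-site duplication length at LTR insertion.
    tsd_length: int = 5

    def validate(self) -> "SimulationConfig":
        if self.n_contigs < 1:
            raise ConfigError("n_contigs must be >= 1")
        if self.contig_length < 1000:
            raise ConfigError("contig_length must be >= 1 kb")
        for name in ("snp_rate", "solo_fraction", "indel_ltr_fraction",
                     "indel_gene_fraction", "indel_gene_silent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.indel_ltr_fraction + self.indel_gene_fraction > 1.0:
            raise ConfigError("indel LTR + gene fractions exceed 1")
        if self.mu <= 0:
            raise ConfigError("mu must be positive")
        lo, hi = self.indel_size_range
        if not lo < hi:
            raise ConfigError("indel_size_range min must be < max")
        self.ltr_age_distribution.validate()
        self.indel_ltr_age_distribution.validate()
        if self.ltr_age_distribution.max_age * self.mu >= 0.75:
            raise ConfigError(
                "mu * max age >= 0.75: LTR divergence would saturate beyond "
                "Jukes-Cantor recoverability"
            )
        if self.coverage_mean < 0 or self.n_replicates < 1:
            raise ConfigError("coverage_mean must be >= 0 and n_replicates >= 1")
        return self

    def with_(self, **kwargs: Any) -> "SimulationConfig":
        """Return a copy with fields replaced (validated)."""
        return replace(self, **kwargs).validate()
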