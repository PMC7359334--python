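"""Simulation configuration for the synthetic sperm-population model.

The simulator emulates a population of sperm cells whose genome is tiled by
regions, each with a mixture over three chromatin particle types — intact
nucleosomes (~150 bp of protected DNA), hexasome-like subnucleosomes
(~110 bp) and tetrasome-like subnucleosomes (~70 bp) — and with region
specific true histone methylation densities (HMD, the percentage of cells
carrying the mark at that locus) for H3K4me3 and H3K27me3.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

PARTICLE_CLASSES = ("NUC", "SUB110", "SUB70")
FEATURE_LABELS = ("promoter", "enhancer", "exon", "intron", "intergenic")
MARKS = ("K4me3", "K27me3")

#: genome-wide particle mixture used for heterogeneous regions; matches the
#: observed read-class split of sperm MNase fragments (~50/14/36%).
HET_MIX = (0.50, 0.14, 0.36)
NUC_MIX = (0.85, 0.05, 0.10)
SUB_MIX = (0.10, 0.20, 0.70)


@dataclass
class RegionSpec:
    """Ground-truth description of one genomic region.

    ``particle_mix`` is the probability that a cell of the population carries
    a (NUC, SUB110, SUB70) particle at a bin of this region; ``true_hmd_*``
    are the percentages of cells methylated at the region for each mark.
    """

    chrom: str
    start: int
    end: int
    particle_mix: tuple[float, float, float]
    true_hmd_k4: float
    true_hmd_k27: float
    feature_label: str

    def validate(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if abs(sum(self.particle_mix) - 1.0) > 1e-8 or min(self.particle_mix) < 0:
            raise ValueError("particle_mix must be a probability triple")
        for v in (self.true_hmd_k4, self.true_hmd_k27):
            if not (0.0 <= v <= 100.0):
                raise ValueError("true HMD must lie in [0, 100]")
        if self.feature_label not in FEATURE_LABELS:
            raise ValueError(f"unknown feature label {self.feature_label!r}")


@dataclass
class SimConfig:
    """Free parameters of the synthetic sperm population.

    Parameters
    ----------
    n_cells
        Population size; each cell carries one particle per 50-bp bin.
    depth
        Mean sequenced fragments per bin; for IP/input simulations the input
        sampling rate is ``depth / n_cells``, so ``depth <= n_cells``.
    ip_efficiency, ip_background
        Capture probability of on-target (methylated) and off-target
        particles during immunoprecipitation.
    ladder_tiers
        Barcoded semi-synthetic nucleosome standards: (barcode_id, mark,
        relative concentration). The default five-tier ladder spans 0.25x to
        64x of the unit concentration so that some standards fall below and
        some above the genome coverage.
    ladder_copies
        Absolute molecule count of a ladder member at relative
        concentration 1.
    retention_coefs
        (intercept, hmd_slope, log_width_slope) of the logistic model for
        peak survival through egg-extract replication.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 300_000
    bin_size_bp: int = 50
    n_cells: int = 100
    depth: float = 30.0
    frag_length_means: tuple[float, float, float] = (150.0, 110.0, 70.0)
    frag_length_sd: float = 8.0
    region_specs: list[RegionSpec] | None = None
    ip_efficiency: float = 0.30
    ip_background: float = 0.0
    ladder_tiers: list[tuple[str, str, float]] = field(default_factory=lambda: [
        (f"BC{mark}{i}", mark, conc)
        for mark in MARKS
        for i, conc in enumerate((0.25, 1.0, 4.0, 16.0, 64.0), start=1)
    ])
    ladder_copies: int = 5000
    retention_coefs: tuple[float, float, float] = (-6.0, 0.06, 0.3)

    def validate(self) -> None:
        for name in ("ip_efficiency", "ip_background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        m = self.frag_length_means
        if not (m[0] > m[1] > m[2] > 0):
            raise ValueError("frag_length_means must be strictly decreasing")
        if self.bin_size_bp <= 0 or self.chrom_length_bp % self.bin_size_bp:
            raise ValueError("chrom_length_bp must be a multiple of bin_size_bp")
        if not (0 < self.depth <= self.n_cells):
            raise ValueError("depth must lie in (0, n_cells]")
        if self.region_specs is not None:
            self._validate_tiling(self.region_specs)

    def _validate_tiling(self, specs: list[RegionSpec]) -> None:
        by_chrom: dict[str, list[RegionSpec]] = {}
        for s in specs:
            s.validate()
            by_chrom.setdefault(s.chrom, []).append(s)
        expect = {self.chrom_name(i) for i in range(self.n_chromosomes)}
        if set(by_chrom) != expect:
            raise ValueError("region specs must cover every chromosome")
        for chrom, rs in by_chrom.items():
            rs = sorted(rs, key=lambda s: s.start)
            pos = 0
            for s in rs:
                if s.start != pos:
                    raise ValueError(
                        f"regions on {chrom} overlap or leave a gap at {pos}")
                pos = s.end
            if pos != self.chrom_length_bp:
                raise ValueError(f"regions on {chrom} do not tile to chromosome end")

    # -- naming helpers -------------------------------------------------
    def chrom_name(self, i: int) -> str:
        return f"chr{i + 1}"

    def chrom_sizes(self) -> dict[str, int]:
        return {self.chrom_name(i): self.chrom_length_bp
                for i in range(self.n_chromosomes)}

    @property
    def n_bins_per_chrom(self) -> int:
        return self.chrom_length_bp // self.bin_size_bp

    # -- reproducible substreams ----------------------------------------
    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed.

        Each operation draws from its own stream so adding operations never
        perturbs the draws of existing ones.
        """
        key = zlib.crc32(stream.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


def config_to_yaml(config: SimConfig, path) -> None:
    d = asdict(config)
    if d["region_specs"] is not None:
        d["region_specs"] = [asdict(s) for s in config.region_specs]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("region_specs"):
        d["region_specs"] = [RegionSpec(**{**s, "particle_mix": tuple(s["particle_mix"])})
                             for s in d["region_specs"]]
    for key in ("frag_length_means", "retention_coefs"):
        if key in d:
            d[key] = tuple(d[key])
    if "ladder_tiers" in d:
        d["ladder_tiers"] = [tuple(t) for t in d["ladder_tiers"]]
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg
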