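"""Synthetic sperm-population generator.

Ground truth is explicit at every level: each of ``n_cells`` cells carries
one particle (nucleosome, 110-bp or 70-bp subnucleosome) per 50-bp bin,
drawn from its region's mixture, plus independent per-cell methylation
states per mark whose Bernoulli rate is the region's true HMD. MNase-seq
fragments, calibrated ChIP (IP/input plus a barcoded spike-in ladder) and a
replication process that preferentially keeps high-HMD, wide peaks are all
derived from this one population, so every downstream inference can be
checked against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (SimConfig, RegionSpec, HET_MIX, NUC_MIX, SUB_MIX,
                     FEATURE_LABELS, MARKS)
from .intervals import overlap_mask

# promoter archetypes cycled along the genome: (name, true HMD K4, true HMD
# K27, particle mix). High-K4, bivalent and high-K27 promoters emulate the
# homogeneously methylated gene subset; the rest are heterogeneous.
PROMOTER_ARCHETYPES = [
    ("k4_high", 90.0, 8.0, NUC_MIX),
    ("bivalent", 88.0, 85.0, SUB_MIX),
    ("k27_high", 10.0, 90.0, SUB_MIX),
    ("low_a", 25.0, 15.0, HET_MIX),
    ("low_b", 5.0, 30.0, HET_MIX),
    ("quiet", 2.0, 5.0, HET_MIX),
]

# cassette tiled along each chromosome (label, length bp)
_CASSETTE = [
    ("promoter", 2000),
    ("exon", 3000),
    ("intron", 5000),
    ("enhancer", 1500),
    ("intergenic", 13_500),
]
CASSETTE_BP = sum(n for _, n in _CASSETTE)


@dataclass
class Genome:
    regions: pd.DataFrame          # chrom,start,end,feature,archetype,p_*,hmd_*
    tss: pd.DataFrame              # gene_id,chrom,tss,strand,archetype
    chrom_sizes: dict[str, int]

    def features(self, label: str) -> pd.DataFrame:
        if label not in FEATURE_LABELS:
            raise ValueError(f"unknown feature {label!r}")
        return self.regions.loc[self.regions["feature"] == label,
                                ["chrom", "start", "end"]].reset_index(drop=True)


@dataclass
class Population:
    """Realized cell population: one particle and methylation state per
    (cell, bin)."""

    config: SimConfig
    genome: Genome
    bin_chrom: np.ndarray          # chrom name per global bin
    bin_start: np.ndarray          # chrom-local bin start per global bin
    bin_region: np.ndarray         # region row index per global bin
    particle: np.ndarray           # int8 (n_cells, n_bins): 0 NUC/1 SUB110/2 SUB70
    meth: dict[str, np.ndarray]    # mark -> bool (n_cells, n_bins)

    @property
    def n_bins(self) -> int:
        return self.particle.shape[1]

    def true_hmd(self, mark: str) -> np.ndarray:
        """Region-truth HMD per global bin (%)."""
        col = "hmd_k4" if mark == "K4me3" else "hmd_k27"
        return self.genome.regions[col].to_numpy()[self.bin_region]


def default_region_specs(config: SimConfig) -> list[RegionSpec]:
    """Deterministic region tiling: repeating promoter/exon/intron/enhancer/
    intergenic cassettes with promoter archetypes cycling genome-wide."""
    specs: list[RegionSpec] = []
    arch_i = 0
    for ci in range(config.n_chromosomes):
        chrom = config.chrom_name(ci)
        pos = 0
        while pos < config.chrom_length_bp:
            for label, span in _CASSETTE:
                if pos >= config.chrom_length_bp:
                    break
                end = min(pos + span, config.chrom_length_bp)
                if label == "promoter":
                    _, k4, k27, mix = PROMOTER_ARCHETYPES[
                        arch_i % len(PROMOTER_ARCHETYPES)]
                    arch_i += 1
                elif label == "enhancer":
                    k4, k27, mix = 40.0, 20.0, NUC_MIX
                elif label == "exon":
                    k4, k27, mix = 10.0, 10.0, HET_MIX
                elif label == "intron":
                    k4, k27, mix = 5.0, 10.0, HET_MIX
                else:
                    k4, k27, mix = 2.0, 5.0, HET_MIX
                specs.append(RegionSpec(chrom, pos, end, mix, k4, k27, label))
                pos = end
    return specs


def generate_genome(config: SimConfig) -> Genome:
    """Region truth table, TSS annotation and chromosome sizes.

    The layout is fully determined by the config (randomness enters only in
    fragment simulation), so identical configs give byte-identical
    annotation files.
    """
    config.validate()
    specs = config.region_specs or default_region_specs(config)
    config._validate_tiling(specs)
    arch_i = 0
    rows = []
    for s in specs:
        if s.feature_label == "promoter" and config.region_specs is None:
            name = PROMOTER_ARCHETYPES[arch_i % len(PROMOTER_ARCHETYPES)][0]
            arch_i += 1
        else:
            name = s.feature_label
        rows.append((s.chrom, s.start, s.end, s.feature_label, name,
                     *s.particle_mix, s.true_hmd_k4, s.true_hmd_k27))
    regions = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "feature", "archetype",
        "p_nuc", "p_sub110", "p_sub70", "hmd_k4", "hmd_k27"])
    regions = regions.sort_values(["chrom", "start"]).reset_index(drop=True)

    proms = regions[regions["feature"] == "promoter"]
    tss = pd.DataFrame({
        "gene_id": [f"g{i + 1:04d}" for i in range(len(proms))],
        "chrom": proms["chrom"].to_numpy(),
        "tss": ((proms["start"] + proms["end"]) // 2).to_numpy(),
        "strand": np.where(np.arange(len(proms)) % 2 == 0, "+", "-"),
        "archetype": proms["archetype"].to_numpy(),
    })
    return Genome(regions=regions, tss=tss, chrom_sizes=config.chrom_sizes())


def simulate_population(config: SimConfig, genome: Genome) -> Population:
    """Draw the latent population (particles and methylation states)."""
    bs = config.bin_size_bp
    regions = genome.regions
    chrom_list, start_list, region_list = [], [], []
    for ci in range(config.n_chromosomes):
        chrom = config.chrom_name(ci)
        starts = np.arange(0, config.chrom_length_bp, bs, dtype=np.int64)
        sub = regions[regions["chrom"] == chrom]
        # region index of each bin via its start coordinate
        idx = np.searchsorted(sub["start"].to_numpy(), starts, side="right") - 1
        chrom_list.append(np.full(len(starts), chrom, dtype=object))
        start_list.append(starts)
        region_list.append(sub.index.to_numpy()[idx])
    bin_chrom = np.concatenate(chrom_list)
    bin_start = np.concatenate(start_list)
    bin_region = np.concatenate(region_list)

    n_bins = len(bin_start)
    p_nuc = regions["p_nuc"].to_numpy()[bin_region]
    p_sub110 = regions["p_sub110"].to_numpy()[bin_region]

    rng = config.rng("population")
    u = rng.random((config.n_cells, n_bins))
    particle = ((u >= p_nuc).astype(np.int8)
                + (u >= p_nuc + p_sub110).astype(np.int8))
    meth = {}
    for mark, col in (("K4me3", "hmd_k4"), ("K27me3", "hmd_k27")):
        p = regions[col].to_numpy()[bin_region] / 100.0
        meth[mark] = rng.random((config.n_cells, n_bins)) < p
    return Population(config=config, genome=genome, bin_chrom=bin_chrom,
                      bin_start=bin_start, bin_region=bin_region,
                      particle=particle, meth=meth)


def _fragment_records(config: SimConfig, pop: Population,
                      cells: np.ndarray, bins: np.ndarray,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Turn (cell, bin) particle picks into fragment coordinates.

    Length ~ Normal(class mean, sd) truncated to > 0; midpoint uniform
    within the bin; fragments shifted inward at chromosome edges so BED
    coordinates stay valid.
    """
    means = np.asarray(config.frag_length_means)
    cls = pop.particle[cells, bins]
    n = len(cls)
    lengths = rng.normal(means[cls], config.frag_length_sd)
    while np.any(lengths <= 0):  # truncation by redraw; negligible at sd=8
        bad = lengths <= 0
        lengths[bad] = rng.normal(means[cls[bad]], config.frag_length_sd)
    lengths = np.maximum(np.rint(lengths).astype(np.int64), 1)
    mids = pop.bin_start[bins] + rng.integers(0, config.bin_size_bp, n)
    starts = mids - lengths // 2
    starts = np.clip(starts, 0, config.chrom_length_bp - lengths)
    df = pd.DataFrame({
        "chrom": pop.bin_chrom[bins],
        "start": starts,
        "end": starts + lengths,
    })
    return df.sort_values(["chrom", "start", "end"],
                          kind="stable").reset_index(drop=True)


def simulate_mnase_fragments(config: SimConfig, pop: Population,
                             rng: np.random.Generator | None = None
                             ) -> pd.DataFrame:
    """Paired-end MNase fragments: per bin ~ Poisson(depth) fragments, each
    from a uniformly sampled cell's particle at that bin."""
    rng = rng or config.rng("mnase")
    counts = rng.poisson(config.depth, pop.n_bins)
    bins = np.repeat(np.arange(pop.n_bins), counts)
    cells = rng.integers(0, config.n_cells, len(bins))
    return _fragment_records(config, pop, cells, bins, rng)


def simulate_icechip(config: SimConfig, pop: Population, mark: str,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Calibrated ChIP for one mark: (IP fragments, input fragments,
    spike-in barcode count table).

    Each (cell, bin) particle enters the input library with probability
    ``depth / n_cells`` and the IP library with probability
    ``ip_efficiency`` if methylated, ``ip_background`` otherwise. The
    barcoded ladder is subject to the same capture model: on-target members
    are fully methylated, off-target members unmethylated.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    rng = rng or config.rng(f"icechip-{mark}")
    s_in = config.depth / config.n_cells
    shape = pop.particle.shape
    meth = pop.meth[mark]

    in_mask = rng.random(shape) < s_in
    capture_p = np.where(meth, config.ip_efficiency, config.ip_background)
    ip_mask = rng.random(shape) < capture_p

    in_cells, in_bins = np.nonzero(in_mask)
    ip_cells, ip_bins = np.nonzero(ip_mask)
    input_frags = _fragment_records(config, pop, in_cells, in_bins, rng)
    ip_frags = _fragment_records(config, pop, ip_cells, ip_bins, rng)

    rows = []
    for barcode_id, bc_mark, conc in config.ladder_tiers:
        n_copies = int(round(conc * config.ladder_copies))
        on_target = bc_mark == mark
        p_ip = config.ip_efficiency if on_target else config.ip_background
        rows.append((barcode_id, bc_mark, conc,
                     int(rng.binomial(n_copies, p_ip)),
                     int(rng.binomial(n_copies, s_in))))
    barcodes = pd.DataFrame(
        rows, columns=["barcode_id", "mark", "tier", "ip_count", "input_count"])
    return ip_frags, input_frags, barcodes


def simulate_peaks(config: SimConfig, genome: Genome, n: int, mark: str,
                   hmd_promoter: tuple[float, float] = (75.0, 15.0),
                   hmd_background: tuple[float, float] = (30.0, 15.0),
                   width_log_mean: float = np.log(800.0),
                   width_log_sd: float = 0.5,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthetic peak set with realistic HMD/width structure.

    Peaks are placed uniformly; peaks overlapping a promoter draw their HMD
    from the high component (methylated histones concentrate on gene
    regulatory regions), others from the background component. Used to
    exercise replication retention at peak counts the bin-level simulation
    cannot cheaply reach.
    """
    rng = rng or config.rng(f"peaks-{mark}")
    chrom_names = [config.chrom_name(i) for i in range(config.n_chromosomes)]
    chroms = rng.choice(chrom_names, n)
    widths = np.maximum(
        np.rint(rng.lognormal(width_log_mean, width_log_sd, n)).astype(np.int64),
        config.bin_size_bp)
    widths = np.minimum(widths, config.chrom_length_bp)
    starts = (rng.random(n) * (config.chrom_length_bp - widths + 1)).astype(np.int64)
    peaks = pd.DataFrame({"chrom": chroms, "start": starts,
                          "end": starts + widths})
    at_prom = overlap_mask(peaks, genome.features("promoter"))
    hmd = np.where(at_prom,
                   rng.normal(*hmd_promoter, n),
                   rng.normal(*hmd_background, n))
    peaks["hmd"] = np.clip(hmd, 0.0, 100.0)
    peaks["mark"] = mark
    return peaks.sort_values(["chrom", "start", "end"],
                             kind="stable").reset_index(drop=True)


def thin_non_overlapping(peaks: pd.DataFrame) -> pd.DataFrame:
    """Greedy maximal non-overlapping subset (sorted by start, keep-first).

    Overlap-based retention calling is only meaningful when peaks within a
    set do not overlap each other; peak callers guarantee this on real
    data, so sparse synthetic sets should too.
    """
    keep = []
    for chrom, sub in peaks.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"], kind="stable")
        last_end = -1
        for idx, row in sub.iterrows():
            if row["start"] >= last_end:
                keep.append(idx)
                last_end = row["end"]
    return peaks.loc[keep].sort_values(["chrom", "start"],
                                       kind="stable").reset_index(drop=True)


def retention_probability(peaks: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Logistic survival probability of each peak through replication."""
    intercept, hmd_slope, log_width_slope = config.retention_coefs
    width = (peaks["end"] - peaks["start"]).to_numpy(dtype=float)
    hmd = peaks["hmd"].to_numpy(dtype=float)
    return expit(intercept + hmd_slope * hmd + log_width_slope * np.log(width))


def simulate_replication(peaks: pd.DataFrame, config: SimConfig,
                         rng: np.random.Generator | None = None,
                         return_lost: bool = False):
    """Egg-extract replication stand-in: each peak survives independently
    with probability logistic(intercept + hmd_slope*HMD +
    log_width_slope*ln(width)); survivors are emitted unchanged."""
    rng = rng or config.rng("replication")
    p = retention_probability(peaks, config)
    keep = rng.random(len(peaks)) < p
    retained = peaks[keep].reset_index(drop=True)
    if return_lost:
        return retained, peaks[~keep].reset_index(drop=True)
    return retained
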