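"""Synthetic population generator: determinism, genome tiling, sampling
statistics against binomial/Poisson oracles, and the capture model."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.special import expit

from spermchrom import simulate as sim
from spermchrom.config import RegionSpec, HET_MIX
from spermchrom.fragments import classify_fragments, read_fractions

from conftest import uniform_config


# ---------------------------------------------------------------- genome
def test_generate_genome_tiles_chromosomes(tiny_config, tiny_genome):
    spans = tiny_genome.regions.groupby("chrom").apply(
        lambda d: int((d["end"] - d["start"]).sum()), include_groups=False)
    assert (spans == tiny_config.chrom_length_bp).all()
    # regions abut without overlap
    for _, sub in tiny_genome.regions.groupby("chrom"):
        assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()


def test_tss_inside_promoters(tiny_genome):
    proms = tiny_genome.features("promoter")
    for rec in tiny_genome.tss.itertuples():
        hit = proms[(proms["chrom"] == rec.chrom)
                    & (proms["start"] <= rec.tss) & (rec.tss < proms["end"])]
        assert len(hit) == 1


def test_single_region_config():
    cfg = uniform_config()
    genome = sim.generate_genome(cfg)
    assert len(genome.regions) == 1
    assert int(genome.regions["end"].iloc[0]) == cfg.chrom_length_bp


def test_overlapping_regions_rejected():
    cfg = uniform_config()
    cfg.region_specs = [
        RegionSpec("chr1", 0, 30_000, HET_MIX, 0, 0, "intergenic"),
        RegionSpec("chr1", 20_000, 50_000, HET_MIX, 0, 0, "intergenic"),
    ]
    with pytest.raises(ValueError, match="overlap|gap"):
        sim.generate_genome(cfg)


def test_gapped_regions_rejected():
    cfg = uniform_config()
    cfg.region_specs = [RegionSpec("chr1", 0, 40_000, HET_MIX, 0, 0,
                                   "intergenic")]
    with pytest.raises(ValueError):
        sim.generate_genome(cfg)


# ---------------------------------------------------------- determinism
def test_same_seed_reproduces_everything():
    cfg = uniform_config(hmd_k4=40.0)
    outs = []
    for _ in range(2):
        genome = sim.generate_genome(cfg)
        pop = sim.simulate_population(cfg, genome)
        frags = sim.simulate_mnase_fragments(cfg, pop)
        ip, inp, barcodes = sim.simulate_icechip(cfg, pop, "K4me3")
        outs.append((frags, ip, inp, barcodes))
    for a, b in zip(outs[0], outs[1]):
        assert_frame_equal(a, b)


def test_substreams_are_independent():
    """Drawing ICeChIP first must not perturb the MNase stream."""
    cfg = uniform_config()
    genome = sim.generate_genome(cfg)
    pop = sim.simulate_population(cfg, genome)
    frags_direct = sim.simulate_mnase_fragments(cfg, pop)
    sim.simulate_icechip(cfg, pop, "K27me3")
    frags_after = sim.simulate_mnase_fragments(cfg, pop)
    assert_frame_equal(frags_direct, frags_after)


# ------------------------------------------------------- MNase sampling
def test_class_fractions_match_mixture():
    """Empirical read-class fractions within 3 binomial SE of the mix.

    A narrow length sd keeps window truncation negligible so the classified
    fractions estimate the mixture itself.
    """
    mix = (0.5, 0.14, 0.36)
    cfg = uniform_config(mix=mix, chrom_length_bp=100_000, depth=50.0,
                         frag_length_sd=4.0)
    genome = sim.generate_genome(cfg)
    pop = sim.simulate_population(cfg, genome)
    frags = classify_fragments(sim.simulate_mnase_fragments(cfg, pop))
    fracs = read_fractions(frags)
    n = len(frags)
    for cls, p in zip(("NUC", "SUB110", "SUB70"), mix):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(fracs[cls] - p) < 3 * se


def test_pure_nucleosome_mix_lengths():
    cfg = uniform_config(mix=(1.0, 0.0, 0.0), frag_length_sd=1e-9)
    genome = sim.generate_genome(cfg)
    pop = sim.simulate_population(cfg, genome)
    frags = sim.simulate_mnase_fragments(cfg, pop)
    assert ((frags["end"] - frags["start"]) == 150).all()


def test_fragment_count_poisson_oracle():
    cfg = uniform_config(depth=20.0)
    genome = sim.generate_genome(cfg)
    pop = sim.simulate_population(cfg, genome)
    frags = sim.simulate_mnase_fragments(cfg, pop)
    expected = cfg.depth * pop.n_bins
    assert abs(len(frags) - expected) < 4 * np.sqrt(expected)


# ----------------------------------------------------------- ICeChIP
def test_icechip_extreme_hmd():
    cfg = uniform_config(hmd_k4=100.0, hmd_k27=0.0, ip_background=0.0)
    genome = sim.generate_genome(cfg)
    pop = sim.simulate_population(cfg, genome)
    ip_k4, inp_k4, _ = sim.simulate_icechip(cfg, pop, "K4me3")
    ip_k27, _, _ = sim.simulate_icechip(cfg, pop, "K27me3")
    assert len(ip_k4) > 0 and len(inp_k4) > 0
    assert len(ip_k27) == 0  # true HMD 0, no background: nothing captured


def test_icechip_rejects_unknown_mark(tiny_config, tiny_population):
    with pytest.raises(ValueError, match="mark"):
        sim.simulate_icechip(tiny_config, tiny_population, "K9me3")


def test_ladder_ratio_estimates_efficiency_over_sampling():
    """On-target pooled IP/input ratio ~ ip_efficiency / input sampling
    rate, independent of genomic content."""
    cfg = uniform_config(hmd_k4=10.0, ip_efficiency=0.3, depth=25.0,
                         n_cells=100)
    genome = sim.generate_genome(cfg)
    pop = sim.simulate_population(cfg, genome)
    _, _, barcodes = sim.simulate_icechip(cfg, pop, "K4me3")
    on = barcodes[barcodes["mark"] == "K4me3"]
    ratio = on["ip_count"].sum() / on["input_count"].sum()
    expected = cfg.ip_efficiency / (cfg.depth / cfg.n_cells)
    n_copies = int(sum(round(c * cfg.ladder_copies)
                       for _, m, c in cfg.ladder_tiers if m == "K4me3"))
    # delta-method SE of the binomial count ratio
    se = expected * np.sqrt((1 - cfg.ip_efficiency) / (n_copies * cfg.ip_efficiency)
                            + (1 - 0.25) / (n_copies * 0.25))
    assert abs(ratio - expected) < 3 * se


# -------------------------------------------------------- replication
def test_replication_extremes():
    peaks = pd.DataFrame({"chrom": "chr1", "start": [0, 100], "end": [50, 400],
                          "hmd": [10.0, 90.0]})
    cfg_all = uniform_config(retention_coefs=(1e6, 0.0, 0.0))
    cfg_none = uniform_config(retention_coefs=(-1e6, 0.0, 0.0))
    assert len(sim.simulate_replication(peaks, cfg_all)) == 2
    assert len(sim.simulate_replication(peaks, cfg_none)) == 0


def test_replication_logistic_closed_form():
    """Coefs (-4, 0.05, 0) at HMD 80: retention ~ logistic(0) = 0.5."""
    n = 10_000
    peaks = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 10,
                          "end": np.arange(n) * 10 + 500,
                          "hmd": np.full(n, 80.0)})
    cfg = uniform_config(retention_coefs=(-4.0, 0.05, 0.0))
    assert np.allclose(sim.retention_probability(peaks, cfg), expit(0.0))
    retained = sim.simulate_replication(peaks, cfg)
    se = np.sqrt(0.25 / n)
    assert abs(len(retained) / n - 0.5) < 3 * se


def test_retention_monotone_in_hmd():
    n = 5_000
    cfg = uniform_config(retention_coefs=(-4.0, 0.05, 0.0))
    fracs = []
    for hmd in (20.0, 90.0):
        peaks = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 10,
                              "end": np.arange(n) * 10 + 500,
                              "hmd": np.full(n, hmd)})
        fracs.append(len(sim.simulate_replication(peaks, cfg)) / n)
    assert fracs[0] < fracs[1]


def test_simulated_peaks_put_high_hmd_at_promoters(tiny_config, tiny_genome):
    from spermchrom.intervals import overlap_mask
    peaks = sim.simulate_peaks(tiny_config, tiny_genome, 500, "K4me3")
    at_prom = overlap_mask(peaks, tiny_genome.features("promoter"))
    assert peaks.loc[at_prom, "hmd"].mean() > peaks.loc[~at_prom, "hmd"].mean()
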