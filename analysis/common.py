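"""Shared study setup for the numbered analysis drivers.

One synthetic sperm population (seed 1, two 300-kb chromosomes, 100 cells,
~30 fragments per 50-bp bin) serves every analysis, so numbers quoted in
one script's output are consistent with the next. All builders are
deterministic in the seed; scripts recompute rather than share state.
"""

from pathlib import Path

import numpy as np

from spermchrom import segmentation as seg
from spermchrom import simulate as sim
from spermchrom.config import SimConfig, MARKS
from spermchrom.fragments import bin_counts, classify_fragments, read_fractions
from spermchrom.hmd import call_peaks, capture_efficiency, hmd_track, peak_hmd, homogeneity_call

STUDY_SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS


def study_config() -> SimConfig:
    return SimConfig(seed=STUDY_SEED)


def build_population(cfg=None):
    cfg = cfg or study_config()
    genome = sim.generate_genome(cfg)
    pop = sim.simulate_population(cfg, genome)
    return cfg, genome, pop


def classified_mnase(cfg, pop):
    return classify_fragments(sim.simulate_mnase_fragments(cfg, pop))


def binned_mnase(cfg, genome, pop):
    return bin_counts(classified_mnase(cfg, pop), cfg.bin_size_bp,
                      genome.chrom_sizes)


def segmentation_for(counts):
    baseline = seg.genome_baseline(counts)
    params, history = seg.fit_hmm(counts, seg.default_params(baseline),
                                  max_iter=30)
    states, segments = seg.decode(counts, params)
    return params, history, states, segments


def hmd_for(cfg, pop, mark):
    ip, inp, barcodes = sim.simulate_icechip(cfg, pop, mark)
    eff, qc = capture_efficiency(barcodes, mark)
    ip_b = bin_counts(classify_fragments(ip), cfg.bin_size_bp,
                      cfg.chrom_sizes())
    in_b = bin_counts(classify_fragments(inp), cfg.bin_size_bp,
                      cfg.chrom_sizes())
    track = hmd_track(ip_b, in_b, eff, mark=mark)
    return track, eff, qc


def peaks_for(cfg, pop, mark):
    track, eff, _ = hmd_for(cfg, pop, mark)
    peaks = peak_hmd(call_peaks(track), track)
    peaks["homogeneity"] = homogeneity_call(peaks["hmd"].to_numpy())
    peaks["mark"] = mark
    return peaks, track


def all_marks(cfg, pop):
    tracks, peak_sets = {}, {}
    for mark in MARKS:
        peaks, track = peaks_for(cfg, pop, mark)
        tracks[mark] = track
        peak_sets[mark] = peaks
    return tracks, peak_sets
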