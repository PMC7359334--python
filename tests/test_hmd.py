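"""Spike-in calibration, apparent HMD tracks, homogeneity calls, bands."""

import numpy as np
import pandas as pd
import pytest

from spermchrom import simulate as sim
from spermchrom.fragments import bin_counts, classify_fragments
from spermchrom.hmd import (capture_efficiency, call_peaks, hmd_band_fractions,
                            hmd_track, homogeneity_call, peak_hmd)

from conftest import uniform_config


def barcode_table(rows):
    return pd.DataFrame(rows, columns=["barcode_id", "mark", "tier",
                                       "ip_count", "input_count"])


def bins(ip, inp, bin_size=50):
    starts = np.arange(len(ip)) * bin_size
    frame = {"chrom": "chr1", "start": starts, "end": starts + bin_size}
    return (pd.DataFrame({**frame, "count": ip}),
            pd.DataFrame({**frame, "count": inp}))


# ------------------------------------------------------- calibration
def test_capture_efficiency_single_barcode():
    eff, _ = capture_efficiency(barcode_table([("b1", "K4me3", 1.0, 500, 1000)]),
                                "K4me3")
    assert eff == 0.5


def test_capture_efficiency_constant_tiers_zero_cv():
    table = barcode_table([("b1", "K4me3", 1.0, 50, 100),
                           ("b2", "K4me3", 4.0, 200, 400),
                           ("b3", "K4me3", 16.0, 800, 1600)])
    eff, qc = capture_efficiency(table, "K4me3")
    assert eff == 0.5
    assert qc.attrs["tier_cv"] == pytest.approx(0.0)


def test_capture_efficiency_errors():
    with pytest.raises(ValueError, match="on-target"):
        capture_efficiency(barcode_table([("b1", "K27me3", 1.0, 5, 10)]),
                           "K4me3")
    with pytest.raises(ValueError, match="input"):
        capture_efficiency(barcode_table([("b1", "K4me3", 1.0, 5, 0)]),
                           "K4me3")


def test_capture_efficiency_high_cv_warns():
    table = barcode_table([("b1", "K4me3", 1.0, 90, 100),
                           ("b2", "K4me3", 4.0, 40, 400)])
    with pytest.warns(UserWarning, match="CV"):
        capture_efficiency(table, "K4me3")


# --------------------------------------------------------- HMD track
def test_hmd_track_ratio_equal_to_efficiency_is_100():
    ip, inp = bins([30, 0], [60, 60])
    track = hmd_track(ip, inp, efficiency=0.5)
    assert track["hmd"].iloc[0] == pytest.approx(100.0)
    assert track["hmd"].iloc[1] == 0.0


def test_hmd_track_low_input_is_na_not_zero():
    ip, inp = bins([3, 3], [4, 5])
    track = hmd_track(ip, inp, efficiency=1.0, min_input=5)
    assert np.isnan(track["hmd"].iloc[0])
    assert track["hmd"].iloc[1] == pytest.approx(60.0)


def test_hmd_track_not_clipped_above_100():
    ip, inp = bins([90], [60])
    track = hmd_track(ip, inp, efficiency=0.5)
    assert track["hmd"].iloc[0] == pytest.approx(300.0)


def test_hmd_scale_equivariance():
    """Doubling the efficiency halves every HMD value exactly."""
    rng = np.random.default_rng(0)
    ip, inp = bins(rng.poisson(10, 50), rng.poisson(30, 50))
    a = hmd_track(ip, inp, efficiency=0.4)["hmd"]
    b = hmd_track(ip, inp, efficiency=0.8)["hmd"]
    np.testing.assert_allclose(b, a / 2)


def test_hmd_track_rejects_bad_efficiency_and_binning():
    ip, inp = bins([1], [10])
    with pytest.raises(ValueError, match="efficiency"):
        hmd_track(ip, inp, efficiency=0.0)
    ip2 = ip.assign(start=[50], end=[100])
    with pytest.raises(ValueError, match="binned"):
        hmd_track(ip2, inp, efficiency=0.5)


def test_hmd_estimator_recovers_truth():
    """True HMD 40, no background: region estimate within 3 SE of 40."""
    cfg = uniform_config(hmd_k4=40.0, ip_background=0.0, depth=30.0,
                         chrom_length_bp=100_000)
    genome = sim.generate_genome(cfg)
    pop = sim.simulate_population(cfg, genome)
    ip, inp, barcodes = sim.simulate_icechip(cfg, pop, "K4me3")
    eff, _ = capture_efficiency(barcodes, "K4me3")
    ip_b = bin_counts(classify_fragments(ip), 50, cfg.chrom_sizes())
    in_b = bin_counts(classify_fragments(inp), 50, cfg.chrom_sizes())
    track = hmd_track(ip_b, in_b, eff)
    region = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                           "end": [cfg.chrom_length_bp]})
    est = peak_hmd(region, track)["hmd"].iloc[0]
    # binomial SE of the pooled IP capture, in HMD points
    n_particles = cfg.n_cells * pop.n_bins
    se = 100 * np.sqrt(0.4 * 0.6 / (n_particles * cfg.ip_efficiency))
    assert abs(est - 40.0) < 3 * max(se, 1.0)


def test_background_inflates_apparent_hmd():
    """Off-target capture makes recovered HMD exceed truth."""
    cfg = uniform_config(hmd_k4=20.0, ip_background=0.1, depth=30.0)
    genome = sim.generate_genome(cfg)
    pop = sim.simulate_population(cfg, genome)
    ip, inp, barcodes = sim.simulate_icechip(cfg, pop, "K4me3")
    eff, _ = capture_efficiency(barcodes, "K4me3")
    ip_b = bin_counts(classify_fragments(ip), 50, cfg.chrom_sizes())
    in_b = bin_counts(classify_fragments(inp), 50, cfg.chrom_sizes())
    track = hmd_track(ip_b, in_b, eff)
    region = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                           "end": [cfg.chrom_length_bp]})
    est = peak_hmd(region, track)["hmd"].iloc[0]
    assert est > 20.0 + 3.0  # expected inflation: (1-m) * b/e ~ +26 points


# ---------------------------------------------------------- peak HMD
def test_peak_hmd_weighted_mean():
    track = pd.DataFrame({"chrom": "chr1", "start": [0, 50],
                          "end": [50, 100], "input_count": [1, 3],
                          "hmd": [0.0, 100.0]})
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
    assert peak_hmd(peaks, track)["hmd"].iloc[0] == pytest.approx(75.0)


def test_peak_hmd_equal_bins():
    track = pd.DataFrame({"chrom": "chr1", "start": [0, 50],
                          "end": [50, 100], "input_count": [5, 5],
                          "hmd": [50.0, 50.0]})
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [90]})
    assert peak_hmd(peaks, track)["hmd"].iloc[0] == pytest.approx(50.0)


def test_peak_hmd_all_na_is_na():
    track = pd.DataFrame({"chrom": "chr1", "start": [0, 50],
                          "end": [50, 100], "input_count": [0, 0],
                          "hmd": [np.nan, np.nan]})
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
    assert np.isnan(peak_hmd(peaks, track)["hmd"].iloc[0])


# -------------------------------------------------- calls and bands
def test_homogeneity_call_boundary():
    assert homogeneity_call(85.0) == "homogeneous"
    assert homogeneity_call(80.0) == "heterogeneous"  # strict inequality
    assert homogeneity_call(float("nan")) == "NA"


def test_band_fractions_examples():
    assert hmd_band_fractions([90.0, 90.0])["(80,inf]"] == 1.0
    fracs = hmd_band_fractions([10.0, 30.0, 90.0])
    assert fracs == {"0": 0.0, "(0,20]": pytest.approx(1 / 3),
                     "(20,40]": pytest.approx(1 / 3), "(40,60]": 0.0,
                     "(60,80]": 0.0, "(80,inf]": pytest.approx(1 / 3)}


def test_band_fractions_sum_to_one():
    rng = np.random.default_rng(1)
    vals = rng.uniform(0, 150, 500)
    assert sum(hmd_band_fractions(vals).values()) == pytest.approx(1.0)


def test_band_fractions_errors():
    with pytest.raises(ValueError, match="edges"):
        hmd_band_fractions([10.0], band_edges=(20.0, 40.0))
    with pytest.raises(ValueError, match="defined"):
        hmd_band_fractions([float("nan")])


def test_call_peaks_finds_hot_run():
    hmdv = [np.nan, 5, 90, 95, 88, 4, np.nan, 91, 3]
    starts = np.arange(len(hmdv)) * 50
    track = pd.DataFrame({"chrom": "chr1", "start": starts,
                          "end": starts + 50, "hmd": hmdv})
    peaks = call_peaks(track, min_hmd=20.0, min_bins=2)
    assert len(peaks) == 1
    assert (peaks.iloc[0]["start"], peaks.iloc[0]["end"]) == (100, 250)
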