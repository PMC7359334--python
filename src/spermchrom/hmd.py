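"""Spike-in calibrated histone methylation density (HMD).

The barcoded semi-synthetic nucleosome ladder shares the IP and the library
sampling with the genomic chromatin, so the on-target standards' pooled
IP/input ratio measures the capture efficiency of a fully methylated locus.
Dividing each bin's IP/input ratio by that efficiency converts enrichment
into an absolute "apparent HMD" percentage — the percentage of histone H3
at the locus carrying the mark across the sperm population. Values above
100 are retained (antibody off-target binding inflates apparent HMD),
hence "apparent".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_MIN_INPUT = 5
HOMOGENEITY_THRESHOLD = 80.0
#: default bands: exactly 0, then (0,20], (20,40], (40,60], (60,80], (80,inf)
DEFAULT_BAND_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0)


def capture_efficiency(barcodes: pd.DataFrame, mark: str,
                       cv_warn: float = 0.25) -> tuple[float, pd.DataFrame]:
    """Pooled IP/input ratio of the on-target ladder standards.

    Pooling counts across tiers is the minimum-variance estimate when all
    tiers share the true ratio; the per-tier ratios and their coefficient
    of variation are returned as ladder QC (a high CV flags a ladder whose
    tiers disagree, e.g. saturation or barcode dropout).
    """
    on = barcodes[barcodes["mark"] == mark]
    if len(on) == 0:
        raise ValueError(f"no on-target barcodes for mark {mark!r}")
    total_input = int(on["input_count"].sum())
    if total_input == 0:
        raise ValueError("zero on-target input counts; ladder unusable")
    efficiency = float(on["ip_count"].sum()) / total_input
    qc = on[["barcode_id", "tier", "ip_count", "input_count"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        qc["ratio"] = qc["ip_count"] / qc["input_count"]
    ratios = qc["ratio"].replace([np.inf, -np.inf], np.nan).dropna()
    cv = float(ratios.std(ddof=1) / ratios.mean()) if len(ratios) > 1 and ratios.mean() > 0 else 0.0
    qc.attrs["tier_cv"] = cv
    if cv > cv_warn:
        warnings.warn(f"ladder tier ratio CV {cv:.2f} exceeds {cv_warn}; "
                      "calibration may be unreliable", stacklevel=2)
    return efficiency, qc


def hmd_track(ip_bins: pd.DataFrame, input_bins: pd.DataFrame,
              efficiency: float, min_input: int = DEFAULT_MIN_INPUT,
              mark: str | None = None) -> pd.DataFrame:
    """Per-bin apparent HMD (%): 100 * (IP/input) / efficiency.

    IP and input must share the binning. Bins with input below
    ``min_input`` are NA (undefined, not zero) so sparse bins do not
    deflate band fractions. Values above 100 are kept.
    """
    if efficiency <= 0:
        raise ValueError("capture efficiency must be positive")
    for col in ("chrom", "start"):
        if not ip_bins[col].equals(input_bins[col]):
            raise ValueError("IP and input tracks are binned differently")
    ip = ip_bins[["n_nuc", "n_sub110", "n_sub70"]].sum(axis=1).to_numpy(dtype=float) \
        if "n_nuc" in ip_bins else ip_bins["count"].to_numpy(dtype=float)
    inp = input_bins[["n_nuc", "n_sub110", "n_sub70"]].sum(axis=1).to_numpy(dtype=float) \
        if "n_nuc" in input_bins else input_bins["count"].to_numpy(dtype=float)
    hmd = np.full(len(ip), np.nan)
    ok = inp >= min_input
    hmd[ok] = 100.0 * (ip[ok] / inp[ok]) / efficiency
    out = pd.DataFrame({
        "chrom": ip_bins["chrom"].to_numpy(),
        "start": ip_bins["start"].to_numpy(),
        "end": ip_bins["end"].to_numpy(),
        "ip_count": ip.astype(np.int64),
        "input_count": inp.astype(np.int64),
        "hmd": hmd,
    })
    out.attrs["efficiency"] = efficiency
    out.attrs["min_input"] = min_input
    if mark is not None:
        out.attrs["mark"] = mark
    return out


def peak_hmd(peaks: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Input-count-weighted mean bin HMD per peak (column ``hmd``).

    Weighting by input counts approximates the HMD that pooling all reads
    across the peak would give. Peaks overlapping only NA bins get NA.
    """
    out = peaks.copy().reset_index(drop=True)
    out["hmd"] = np.nan
    bin_size = int(track["end"].iloc[0] - track["start"].iloc[0])
    for chrom, tsub in track.groupby("chrom"):
        starts = tsub["start"].to_numpy()
        hmd = tsub["hmd"].to_numpy()
        weights = tsub["input_count"].to_numpy(dtype=float)
        sel = np.flatnonzero((out["chrom"] == chrom).to_numpy())
        for i in sel:
            s, e = int(out.at[i, "start"]), int(out.at[i, "end"])
            lo = np.searchsorted(starts, s - bin_size + 1, side="left")
            hi = np.searchsorted(starts, e, side="left")
            h = hmd[lo:hi]
            w = weights[lo:hi]
            ok = ~np.isnan(h)
            if ok.any() and w[ok].sum() > 0:
                out.at[i, "hmd"] = float(np.average(h[ok], weights=w[ok]))
    return out


def homogeneity_call(hmd) -> object:
    """'homogeneous' iff apparent HMD > 80 (strict), else 'heterogeneous';
    NA propagates."""
    scalar = np.isscalar(hmd) or hmd is None
    arr = np.atleast_1d(np.asarray(hmd, dtype=float))
    out = np.where(np.isnan(arr), "NA",
                   np.where(arr > HOMOGENEITY_THRESHOLD,
                            "homogeneous", "heterogeneous"))
    return out[0] if scalar else out


def hmd_band_fractions(values, band_edges=DEFAULT_BAND_EDGES) -> dict[str, float]:
    """Fraction of defined values per apparent-HMD band.

    Bands are [0], (e0, e1], ..., (e_last, inf); edges must start at 0 so
    the bands partition [0, inf).
    """
    edges = tuple(band_edges)
    if len(edges) < 1 or edges[0] != 0.0 or list(edges) != sorted(edges):
        raise ValueError("band edges must be increasing and start at 0")
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        raise ValueError("no defined values")
    labels = ["0"]
    counts = [int((arr == 0.0).sum())]
    bounds = list(edges) + [np.inf]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        labels.append(f"({lo:g},{hi:g}]")
        counts.append(int(((arr > lo) & (arr <= hi)).sum()))
    total = len(arr)
    return {lab: c / total for lab, c in zip(labels, counts)}


def call_peaks(track: pd.DataFrame, min_hmd: float = 20.0,
               min_bins: int = 2, merge_gap_bins: int = 1) -> pd.DataFrame:
    """Trivial fixture peak caller: maximal runs of bins with defined HMD
    above ``min_hmd``, allowing gaps up to ``merge_gap_bins`` bins, kept if
    at least ``min_bins`` long. Stands in for an external peak caller so
    downstream peak analyses are exercisable end to end."""
    peaks = []
    for chrom, sub in track.groupby("chrom"):
        hot = np.flatnonzero((sub["hmd"] > min_hmd).fillna(False).to_numpy())
        if len(hot) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_start = hot[0]
        prev = hot[0]
        for b in list(hot[1:]) + [None]:
            if b is None or b - prev > merge_gap_bins + 1:
                if prev - run_start + 1 >= min_bins:
                    peaks.append((chrom, int(starts[run_start]), int(ends[prev])))
                run_start = b
            prev = b if b is not None else prev
    return pd.DataFrame(peaks, columns=["chrom", "start", "end"])
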