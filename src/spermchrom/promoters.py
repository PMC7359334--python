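"""Promoter feature matrices and PAM (k-medoids) clustering.

Each gene's promoter (TSS +/- 2 kb) is divided into twenty 200-bp bins,
oriented upstream-to-downstream relative to transcription, and filled from
HMD tracks and particle-state segmentations — either as continuous values
(mean bin HMD, state fraction) or as binary homogeneity flags (HMD > 80;
majority homogeneous particle state). Genes are clustered by partitioning
around medoids on the flattened bins x channels vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .hmd import HOMOGENEITY_THRESHOLD
from .segmentation import NO_DATA

N_BINS = 20
FLANK_BP = 2000
BIN_BP = 2 * FLANK_BP // N_BINS  # 200


@dataclass
class PromoterMatrix:
    genes: list[str]
    channels: list[str]
    data: np.ndarray  # (n_genes, N_BINS, n_channels)

    def flat(self) -> np.ndarray:
        return self.data.reshape(len(self.genes), -1)


@dataclass
class ClusterResult:
    assignments: pd.Series      # gene -> cluster id (0-based)
    medoids: list[str]          # gene ids
    total_dissimilarity: float


def _bin_values(track: pd.DataFrame, chrom: str, lo: int, hi: int,
                value_col: str) -> np.ndarray:
    """Mean of ``value_col`` over the N_BINS 200-bp windows of [lo, hi)."""
    sub = track[track["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    vals = sub[value_col].to_numpy(dtype=float)
    src_bin = int(sub["end"].iloc[0] - sub["start"].iloc[0])
    out = np.full(N_BINS, np.nan)
    for b in range(N_BINS):
        ws, we = lo + b * BIN_BP, lo + (b + 1) * BIN_BP
        i0 = np.searchsorted(starts, ws - src_bin + 1, side="left")
        i1 = np.searchsorted(starts, we, side="left")
        v = vals[i0:i1]
        v = v[~np.isnan(v)]
        if len(v):
            out[b] = v.mean()
    return out


def _bin_states(states_track: pd.DataFrame, chrom: str, lo: int, hi: int,
                homogeneous_state: str, binary: bool) -> np.ndarray:
    """Per 200-bp window: fraction of source bins in ``homogeneous_state``
    (continuous) or the majority flag (binary)."""
    sub = states_track[states_track["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    st = sub["state"].to_numpy()
    src_bin = int(sub["end"].iloc[0] - sub["start"].iloc[0])
    out = np.full(N_BINS, np.nan)
    for b in range(N_BINS):
        ws, we = lo + b * BIN_BP, lo + (b + 1) * BIN_BP
        i0 = np.searchsorted(starts, ws - src_bin + 1, side="left")
        i1 = np.searchsorted(starts, we, side="left")
        s = st[i0:i1]
        s = s[s != NO_DATA]
        if len(s) == 0:
            continue
        frac = float((s == homogeneous_state).mean())
        out[b] = float(frac > 0.5) if binary else frac
    return out


def build_promoter_matrix(tss: pd.DataFrame,
                          hmd_tracks: dict[str, pd.DataFrame] | None = None,
                          states_track: pd.DataFrame | None = None,
                          chrom_sizes: dict[str, int] | None = None,
                          mode: str = "continuous") -> PromoterMatrix:
    """Genes x 20 bins x channels matrix around each TSS.

    ``hmd_tracks`` maps channel names (e.g. HMD_K4) to per-bin HMD tracks;
    ``states_track`` is a per-bin table with a ``state`` column supplying
    NUC_enrich / SUB_enrich channels. In binary mode HMD channels become
    homogeneity flags (HMD > 80) and state channels majority flags.
    Minus-strand genes have their bin order reversed; genes within 2 kb of
    a chromosome edge are dropped with a warning.
    """
    if mode not in ("continuous", "binary"):
        raise ValueError("mode must be 'continuous' or 'binary'")
    hmd_tracks = hmd_tracks or {}
    channels = list(hmd_tracks)
    if states_track is not None:
        channels += ["NUC_enrich", "SUB_enrich"]
    if not channels:
        raise ValueError("no channels supplied")
    genes, rows = [], []
    dropped = 0
    for rec in tss.sort_values("gene_id").itertuples():
        lo, hi = rec.tss - FLANK_BP, rec.tss + FLANK_BP
        size = (chrom_sizes or {}).get(rec.chrom)
        if lo < 0 or (size is not None and hi > size):
            dropped += 1
            continue
        mat = np.empty((N_BINS, len(channels)))
        ci = 0
        for name, track in hmd_tracks.items():
            v = _bin_values(track, rec.chrom, lo, hi, "hmd")
            if mode == "binary":
                with np.errstate(invalid="ignore"):
                    v = np.where(np.isnan(v), np.nan,
                                 (v > HOMOGENEITY_THRESHOLD).astype(float))
            mat[:, ci] = v
            ci += 1
        if states_track is not None:
            mat[:, ci] = _bin_states(states_track, rec.chrom, lo, hi,
                                     "HOM_NUC", mode == "binary")
            mat[:, ci + 1] = _bin_states(states_track, rec.chrom, lo, hi,
                                         "HOM_SUB", mode == "binary")
        if rec.strand == "-":
            mat = mat[::-1]
        genes.append(rec.gene_id)
        rows.append(mat)
    if dropped:
        warnings.warn(f"dropped {dropped} genes within {FLANK_BP} bp of a "
                      "chromosome edge", stacklevel=2)
    return PromoterMatrix(genes=genes, channels=channels,
                          data=np.stack(rows) if rows else
                          np.empty((0, N_BINS, len(channels))))


def impute_and_filter(matrix: PromoterMatrix,
                      max_na_frac: float = 0.5) -> PromoterMatrix:
    """Drop genes with more than ``max_na_frac`` NA bins, impute the rest
    with the per-channel median."""
    na = np.isnan(matrix.data).reshape(len(matrix.genes), -1)
    keep = na.mean(axis=1) <= max_na_frac
    data = matrix.data[keep].copy()
    for c in range(data.shape[2]):
        med = np.nanmedian(data[:, :, c])
        if np.isnan(med):
            med = 0.0
        chan = data[:, :, c]
        chan[np.isnan(chan)] = med
    return PromoterMatrix(genes=[g for g, k in zip(matrix.genes, keep) if k],
                          channels=matrix.channels, data=data)


def _standardize(flat: np.ndarray, n_channels: int) -> np.ndarray:
    """Zero mean / unit variance per channel (HMD percentages and
    enrichment fractions live on different scales)."""
    x = flat.reshape(flat.shape[0], N_BINS, n_channels).copy()
    for c in range(n_channels):
        mu = x[:, :, c].mean()
        sd = x[:, :, c].std()
        x[:, :, c] = (x[:, :, c] - mu) / (sd if sd > 0 else 1.0)
    return x.reshape(flat.shape[0], -1)


def pam_cluster(matrix: PromoterMatrix, k: int, seed: int = 0,
                standardize: bool = True, max_iter: int = 100) -> ClusterResult:
    """Partitioning around medoids under Euclidean dissimilarity.

    Greedy k-medoids++-style BUILD seeded from ``seed``, then SWAP passes
    until no single medoid exchange lowers the total dissimilarity. The
    objective never increases, so termination is guaranteed.
    """
    n = len(matrix.genes)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} genes")
    flat = matrix.flat()
    if np.isnan(flat).any():
        raise ValueError("matrix contains NA; run impute_and_filter first")
    if standardize:
        flat = _standardize(flat, len(matrix.channels))
    dist = cdist(flat, flat)
    rng = np.random.default_rng(seed)

    # BUILD: first medoid ~ seeded uniform, then farthest-point style greedy
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        dmin = dist[:, medoids].min(axis=1)
        total = dmin.sum()
        if total <= 0:
            candidates = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(candidates[0]))
            continue
        probs = dmin / total
        medoids.append(int(rng.choice(n, p=probs)))

    def objective(meds):
        return dist[:, meds].min(axis=1).sum()

    best = objective(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = cand
                obj = objective(trial)
                if obj < best - 1e-12:
                    medoids, best, improved = trial, obj, True
        if not improved:
            break

    labels = np.argmin(dist[:, medoids], axis=1)
    # medoids belong to their own cluster by construction (distance 0)
    assignments = pd.Series(labels, index=matrix.genes, name="cluster")
    return ClusterResult(assignments=assignments,
                         medoids=[matrix.genes[m] for m in medoids],
                         total_dissimilarity=float(best))


def cluster_mean_profiles(result: ClusterResult,
                          matrix: PromoterMatrix) -> dict[int, np.ndarray]:
    """Arithmetic mean (bins x channels) profile per cluster."""
    out = {}
    labels = result.assignments.to_numpy()
    for c in np.unique(labels):
        out[int(c)] = matrix.data[labels == c].mean(axis=0)
    return out
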