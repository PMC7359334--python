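"""Half-open genomic interval arithmetic shared across the pipeline.

All coordinates are 0-based half-open (BED convention). Interval tables are
pandas DataFrames with at least ``chrom``, ``start`` and ``end`` columns.
Overlap queries are vectorized: features are merged per chromosome into
sorted disjoint intervals and queries resolved by binary search, which keeps
permutation loops with thousands of randomizations cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def merge_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping/abutting intervals per chromosome.

    Returns ``{chrom: (starts, ends)}`` with sorted, disjoint intervals.
    """
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        order = np.argsort(s, kind="stable")
        s, e = s[order], e[order]
        out_s, out_e = [], []
        cur_s, cur_e = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= cur_e:  # overlapping or abutting
                cur_e = max(cur_e, e[i])
            else:
                out_s.append(cur_s)
                out_e.append(cur_e)
                cur_s, cur_e = s[i], e[i]
        out_s.append(cur_s)
        out_e.append(cur_e)
        merged[chrom] = (np.asarray(out_s, dtype=np.int64),
                         np.asarray(out_e, dtype=np.int64))
    return merged


def overlap_mask(query: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it share >= 1 bp with any feature?"""
    merged = merge_intervals(features) if len(features) else {}
    mask = np.zeros(len(query), dtype=bool)
    if not merged or not len(query):
        return mask
    pos = 0
    # preserve input order: work on positional indices per chromosome
    chroms = query["chrom"].to_numpy()
    qs = query["start"].to_numpy(dtype=np.int64)
    qe = query["end"].to_numpy(dtype=np.int64)
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        if chrom not in merged:
            continue
        fs, fe = merged[chrom]
        # first merged interval whose end > query start
        j = np.searchsorted(fe, qs[sel], side="right")
        ok = j < len(fs)
        hit = np.zeros(len(sel), dtype=bool)
        hit[ok] = fs[j[ok]] < qe[sel][ok]
        mask[sel] = hit
    return mask


def overlap_count(query: pd.DataFrame, features: pd.DataFrame) -> int:
    """Number of query intervals overlapping at least one feature."""
    return int(overlap_mask(query, features).sum())


def randomize_intervals(intervals: pd.DataFrame,
                        chrom_sizes: dict[str, int],
                        rng: np.random.Generator) -> pd.DataFrame:
    """Re-place each interval uniformly on its own chromosome.

    Length and chromosome assignment are preserved; placements may collide
    (the null allows overlaps between randomized intervals).
    """
    chroms = intervals["chrom"].to_numpy()
    lengths = (intervals["end"] - intervals["start"]).to_numpy(dtype=np.int64)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if np.any(lengths > sizes):
        bad = chroms[lengths > sizes][0]
        raise ValueError(f"interval longer than chromosome {bad}")
    # uniform start in [0, size - length]; no wrap-around
    starts = (rng.random(len(intervals)) * (sizes - lengths + 1)).astype(np.int64)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lengths})
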