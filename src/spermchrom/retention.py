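"""Peak retention through replication, replicate consensus, and bivalency.

A reference (sperm) peak is "retained" in a later condition (egg-extract
replicated chromatin, or blastula) iff it shares at least one base with a
peak called there; retained and lost subsets partition the reference set.
HMD and width distributions of retained vs lost peaks are compared with
the two-sample Kolmogorov–Smirnov test, always on the reference-condition
values (the question is what distinguished the peaks *before* replication).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hmd import HOMOGENEITY_THRESHOLD
from .intervals import overlap_mask


@dataclass
class RetentionResult:
    retained: pd.DataFrame
    lost: pd.DataFrame
    n_reference: int
    n_retained: int

    @property
    def percent_retained(self) -> float:
        return 100.0 * self.n_retained / self.n_reference


def consensus_peaks(replicates: list[pd.DataFrame],
                    min_support: int = 2) -> pd.DataFrame:
    """Merged intervals supported by >= min_support replicates.

    Peaks from all replicates are pooled and chained into connected
    components by >= 1 bp overlap; a component is kept if peaks from at
    least ``min_support`` distinct replicates contribute, and its emitted
    coordinates are the union span of the supporting intervals.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicate sets")
    if min_support > len(replicates):
        raise ValueError("min_support exceeds the number of replicates")
    pooled = pd.concat(
        [r.assign(_rep=i)[["chrom", "start", "end", "_rep"]]
         for i, r in enumerate(replicates)], ignore_index=True)
    rows = []
    for chrom, sub in pooled.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"], kind="stable")
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        reps = sub["_rep"].to_numpy()
        cur_s, cur_e = s[0], e[0]
        cur_reps = {reps[0]}
        for i in range(1, len(s)):
            if s[i] < cur_e:  # >=1 bp overlap with the growing component
                cur_e = max(cur_e, e[i])
                cur_reps.add(reps[i])
            else:
                if len(cur_reps) >= min_support:
                    rows.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e, cur_reps = s[i], e[i], {reps[i]}
        if len(cur_reps) >= min_support:
            rows.append((chrom, int(cur_s), int(cur_e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def classify_retention(reference: pd.DataFrame,
                       after: pd.DataFrame) -> RetentionResult:
    """Partition reference peaks into retained (>= 1 bp overlap with any
    `after` peak) and lost."""
    if "mark" in reference.columns and "mark" in after.columns:
        ref_marks = set(reference["mark"].unique())
        aft_marks = set(after["mark"].unique())
        if ref_marks and aft_marks and ref_marks != aft_marks:
            raise ValueError(f"mark mismatch: {ref_marks} vs {aft_marks}")
    mask = overlap_mask(reference, after)
    return RetentionResult(retained=reference[mask].reset_index(drop=True),
                           lost=reference[~mask].reset_index(drop=True),
                           n_reference=len(reference),
                           n_retained=int(mask.sum()))


def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test (D, p); exact p for
    small samples, asymptotic otherwise (scipy's auto policy)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bivalency_classify(k4_peaks: pd.DataFrame,
                       k27_peaks: pd.DataFrame,
                       hmd_threshold: float = HOMOGENEITY_THRESHOLD
                       ) -> dict[str, pd.DataFrame]:
    """Partition homogeneous peaks into K4-only / K27-only / bivalent.

    Homogeneous = peak HMD > threshold. A homogeneous K4 peak overlapping
    (>= 1 bp) a homogeneous K27 peak is bivalent, and vice versa; bivalent
    holds peaks of both marks (a ``mark`` column distinguishes them).
    """
    k4 = k4_peaks[k4_peaks["hmd"] > hmd_threshold].reset_index(drop=True)
    k27 = k27_peaks[k27_peaks["hmd"] > hmd_threshold].reset_index(drop=True)
    k4 = k4.assign(mark="K4me3")
    k27 = k27.assign(mark="K27me3")
    k4_biv = overlap_mask(k4, k27)
    k27_biv = overlap_mask(k27, k4)
    return {
        "K4_only": k4[~k4_biv].reset_index(drop=True),
        "K27_only": k27[~k27_biv].reset_index(drop=True),
        "bivalent": pd.concat([k4[k4_biv], k27[k27_biv]],
                              ignore_index=True),
    }


def category_retention_fractions(categories: dict[str, pd.DataFrame],
                                 after_sets: dict[str, pd.DataFrame]
                                 ) -> dict[str, float]:
    """Fraction of each bivalency category retained after replication.

    Each peak is checked against the post-replication set of its own mark.
    Empty categories yield NA with a warning.
    """
    out: dict[str, float] = {}
    for name, peaks in categories.items():
        if len(peaks) == 0:
            warnings.warn(f"category {name!r} is empty", stacklevel=2)
            out[name] = float("nan")
            continue
        retained = 0
        for mark, sub in peaks.groupby("mark"):
            after = after_sets[mark]
            retained += int(overlap_mask(sub.reset_index(drop=True),
                                         after).sum())
        out[name] = retained / len(peaks)
    return out
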