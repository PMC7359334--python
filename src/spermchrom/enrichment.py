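"""Randomization-based fold enrichment of interval sets at genomic features.

The null re-places each query interval uniformly on its own chromosome with
length preserved (collisions between randomized intervals allowed). Fold =
observed / mean(random) overlap counts; empirical p-values use the add-one
estimator, so the smallest achievable p with N randomizations is
1 / (N + 1) and p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import merge_intervals, overlap_count, overlap_mask, randomize_intervals

__all__ = ["EnrichmentResult", "fold_enrichment", "retained_vs_lost_ratio",
           "overlap_count", "overlap_mask", "randomize_intervals"]


@dataclass
class EnrichmentResult:
    feature: str
    observed: int
    random_mean: float
    random_sd: float
    fold: float
    p_enrichment: float
    p_depletion: float
    n_iterations: int

    def to_row(self) -> dict:
        return {
            "feature": self.feature, "observed": self.observed,
            "random_mean": self.random_mean, "random_sd": self.random_sd,
            "fold": self.fold, "p_enrichment": self.p_enrichment,
            "p_depletion": self.p_depletion, "n_iterations": self.n_iterations,
        }


def fold_enrichment(query: pd.DataFrame, features: pd.DataFrame,
                    chrom_sizes: dict[str, int], n_iterations: int = 1000,
                    seed: int = 0, feature_label: str = "feature",
                    rng: np.random.Generator | None = None) -> EnrichmentResult:
    """Observed/random fold enrichment of query intervals at features.

    Overlap is counted per query interval (>= 1 shared bp). Both tail
    p-values are reported: enrichment p = (1 + #{random >= observed}) /
    (N + 1), depletion the mirrored tail.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    merged = merge_intervals(features) if len(features) else {}

    def count(df):
        # inline overlap against the pre-merged features for speed
        total = 0
        chroms = df["chrom"].to_numpy()
        qs = df["start"].to_numpy(dtype=np.int64)
        qe = df["end"].to_numpy(dtype=np.int64)
        for chrom in np.unique(chroms):
            if chrom not in merged:
                continue
            sel = chroms == chrom
            fs, fe = merged[chrom]
            j = np.searchsorted(fe, qs[sel], side="right")
            ok = j < len(fs)
            total += int(np.count_nonzero(fs[j[ok]] < qe[sel][ok]))
        return total

    observed = count(query)
    random_counts = np.empty(n_iterations, dtype=np.int64)
    for i in range(n_iterations):
        random_counts[i] = count(randomize_intervals(query, chrom_sizes, rng))
    mean = float(random_counts.mean())
    sd = float(random_counts.std(ddof=1)) if n_iterations > 1 else 0.0
    fold = observed / mean if mean > 0 else (np.inf if observed > 0 else np.nan)
    p_enr = (1 + int((random_counts >= observed).sum())) / (n_iterations + 1)
    p_dep = (1 + int((random_counts <= observed).sum())) / (n_iterations + 1)
    return EnrichmentResult(feature=feature_label, observed=observed,
                            random_mean=mean, random_sd=sd, fold=float(fold),
                            p_enrichment=p_enr, p_depletion=p_dep,
                            n_iterations=n_iterations)


def enrichment_table(query: pd.DataFrame,
                     feature_sets: dict[str, pd.DataFrame],
                     chrom_sizes: dict[str, int], n_iterations: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """fold_enrichment against several feature classes; one row each.

    No multiple-testing correction is applied across features: per-feature
    empirical p-values are reported against a fixed significance threshold.
    """
    rows = []
    for i, (label, feats) in enumerate(sorted(feature_sets.items())):
        res = fold_enrichment(query, feats, chrom_sizes, n_iterations,
                              seed=seed + i, feature_label=label)
        rows.append(res.to_row())
    return pd.DataFrame(rows)


def retained_vs_lost_ratio(retained: EnrichmentResult,
                           lost: EnrichmentResult) -> float:
    """Ratio of fold enrichments (retained / lost) at one feature class;
    NA when the lost fold is zero."""
    if retained.feature != lost.feature:
        raise ValueError("feature labels differ between retained and lost")
    if lost.fold == 0:
        return float("nan")
    return retained.fold / lost.fold
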