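"""Gene-level association statistics.

Gene-set membership of peak categories is tested with the one-sample
chi-square proportion test: is the fraction of set genes carrying the peak
category higher (or lower) than the genome-wide fraction p0? The one-sided
p comes from the signed square root of the chi-square statistic (the score
z), with no continuity correction by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSetTest:
    label: str
    n: int                 # genes in the set
    k: int                 # set genes carrying the category
    p0: float              # genome-wide proportion
    alternative: str       # 'greater' or 'less'
    statistic: float       # chi-square (1 df)
    pvalue: float          # one-sided

    def to_row(self) -> dict:
        return {"label": self.label, "n": self.n, "k": self.k, "p0": self.p0,
                "alternative": self.alternative, "statistic": self.statistic,
                "pvalue": self.pvalue}


def proportion_test(k: int, n: int, p0: float, alternative: str = "greater",
                    label: str = "", continuity: bool = False) -> GeneSetTest:
    """One-sample chi-square proportion test of k/n against p0.

    statistic = (phat - p0)^2 / (p0 (1 - p0) / n); the one-sided p is the
    normal tail of the signed root z = (phat - p0) / sqrt(p0 (1 - p0) / n).
    """
    if n < 1 or not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n, n >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly in (0, 1)")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    phat = k / n
    diff = phat - p0
    if continuity:
        corr = min(0.5 / n, abs(diff))
        diff = np.sign(diff) * (abs(diff) - corr)
    se = np.sqrt(p0 * (1.0 - p0) / n)
    z = diff / se
    stat = z * z
    p = stats.norm.sf(z) if alternative == "greater" else stats.norm.cdf(z)
    return GeneSetTest(label=label, n=n, k=k, p0=p0, alternative=alternative,
                       statistic=float(stat), pvalue=float(p))


def assign_peaks_to_genes(peaks: pd.DataFrame, tss: pd.DataFrame,
                          window_bp: int = 2000,
                          category_col: str | None = None) -> pd.DataFrame:
    """Gene x category flag table: a gene carries a category iff a peak of
    that category overlaps TSS +/- window_bp.

    Without ``category_col`` a single ``peak`` flag is produced.
    """
    if tss["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in TSS annotation")
    promoters = pd.DataFrame({
        "chrom": tss["chrom"].to_numpy(),
        "start": np.maximum(tss["tss"].to_numpy() - window_bp, 0),
        "end": tss["tss"].to_numpy() + window_bp,
    })
    from .intervals import overlap_mask
    categories = ([None] if category_col is None
                  else sorted(peaks[category_col].unique()))
    out = pd.DataFrame({"gene_id": tss["gene_id"].to_numpy()})
    for cat in categories:
        sub = peaks if cat is None else peaks[peaks[category_col] == cat]
        name = "peak" if cat is None else str(cat)
        out[name] = overlap_mask(promoters, sub)
    return out.set_index("gene_id")


def gene_set_tests(gene_flags: pd.DataFrame,
                   gene_sets: dict[str, list[str]],
                   alternative: str = "greater") -> pd.DataFrame:
    """proportion_test of each flag column within each gene set.

    The genome-wide proportion p0 is computed from all genes in
    ``gene_flags`` (genes with usable promoters).
    """
    rows = []
    for set_label, genes in sorted(gene_sets.items()):
        present = [g for g in genes if g in gene_flags.index]
        if not present:
            warnings.warn(f"gene set {set_label!r} has no usable genes",
                          stacklevel=2)
            continue
        sub = gene_flags.loc[present]
        for col in gene_flags.columns:
            p0 = float(gene_flags[col].mean())
            if not (0.0 < p0 < 1.0):
                continue  # category absent or universal: test undefined
            res = proportion_test(int(sub[col].sum()), len(sub), p0,
                                  alternative=alternative,
                                  label=f"{set_label}:{col}")
            rows.append(res.to_row())
    return pd.DataFrame(rows)


def ortholog_overlap(genes_a: set[str], genes_b: set[str],
                     ortholog_map: dict[str, str]) -> dict[str, float]:
    """Percentage of genes with peaks in both species.

    ``ortholog_map`` is one-to-one a -> b. Reports the forward percentage
    (|map(A) ∩ B| / |A with orthologs|), the reciprocal, and the counts of
    genes excluded for lacking an ortholog.
    """
    if len(set(ortholog_map.values())) != len(ortholog_map):
        raise ValueError("ortholog map is not one-to-one")
    a_mapped = {g: ortholog_map[g] for g in genes_a if g in ortholog_map}
    inverse = {v: k for k, v in ortholog_map.items()}
    b_mapped = {g: inverse[g] for g in genes_b if g in inverse}
    pct_a = (100.0 * sum(v in genes_b for v in a_mapped.values()) / len(a_mapped)
             if a_mapped else float("nan"))
    pct_b = (100.0 * sum(v in genes_a for v in b_mapped.values()) / len(b_mapped)
             if b_mapped else float("nan"))
    return {"pct_a_in_b": pct_a, "pct_b_in_a": pct_b,
            "n_a_unmapped": len(genes_a) - len(a_mapped),
            "n_b_unmapped": len(genes_b) - len(b_mapped)}


def stratify_5mc(peaks: pd.DataFrame, mc_col: str = "mc_pct",
                 hmd_col: str = "hmd",
                 strata: tuple[tuple[float, float], ...] = ((0.0, 80.0),
                                                           (80.0, np.inf))
                 ) -> pd.DataFrame:
    """Per-HMD-stratum mean 5mC (%), SEM and fraction of peaks with zero
    5mC. Default strata: 0 < HMD <= 80 and HMD > 80."""
    mc = peaks[mc_col].to_numpy(dtype=float)
    if np.any((mc < 0) | (mc > 100)):
        raise ValueError("5mC percentages must lie in [0, 100]")
    hmd = peaks[hmd_col].to_numpy(dtype=float)
    rows = []
    for lo, hi in strata:
        sel = (hmd > lo) & (hmd <= hi)
        label = f"({lo:g},{hi:g}]"
        if not sel.any():
            warnings.warn(f"empty HMD stratum {label}", stacklevel=2)
            rows.append((label, 0, np.nan, np.nan, np.nan))
            continue
        vals = mc[sel]
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append((label, int(sel.sum()), float(vals.mean()), sem,
                     float((vals == 0).mean())))
    return pd.DataFrame(rows, columns=["stratum", "n", "mean_mc", "sem_mc",
                                       "frac_zero_mc"])


def accessibility_test(atac_categories: dict[str, list[str]],
                       high_hmd_genes: set[str],
                       universe: list[str]) -> pd.DataFrame:
    """Enrichment/depletion of high-HMD TSSs per ATAC accessibility class.

    ``atac_categories`` (open / closed / divergent) must partition the
    tested genes; every category is tested in both directions against the
    genome-wide proportion of high-HMD genes in ``universe``.
    """
    seen: set[str] = set()
    for genes in atac_categories.values():
        g = set(genes)
        if seen & g:
            raise ValueError("ATAC categories overlap")
        seen |= g
    p0 = len(high_hmd_genes & set(universe)) / len(universe)
    if not (0.0 < p0 < 1.0):
        raise ValueError("genome-wide high-HMD proportion degenerate")
    rows = []
    for cat, genes in sorted(atac_categories.items()):
        n = len(genes)
        if n == 0:
            continue
        k = len(set(genes) & high_hmd_genes)
        for alt in ("greater", "less"):
            rows.append(proportion_test(k, n, p0, alternative=alt,
                                        label=cat).to_row())
    return pd.DataFrame(rows)
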