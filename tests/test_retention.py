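"""Consensus peaks, retention classification, KS comparison, bivalency."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spermchrom.retention import (RetentionResult, bivalency_classify,
                                  category_retention_fractions,
                                  classify_retention, consensus_peaks,
                                  ks_compare)


def peaks(rows, **extra):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    for k, v in extra.items():
        df[k] = v
    return df


# ----------------------------------------------------------- consensus
def test_consensus_identical_triplicates():
    rep = peaks([("chr1", 0, 100), ("chr1", 500, 700)])
    out = consensus_peaks([rep, rep.copy(), rep.copy()], min_support=2)
    assert out.equals(rep)


def test_consensus_excludes_singleton_support():
    a = peaks([("chr1", 0, 100)])
    b = peaks([("chr1", 5000, 5100)])
    c = peaks([("chr1", 5050, 5150)])
    out = consensus_peaks([a, b, c], min_support=2)
    assert len(out) == 1
    assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (5000, 5150)


def test_consensus_staggered_hand_enumeration():
    """Three replicates with staggered intervals: components and support
    counted by hand."""
    r1 = peaks([("chr1", 0, 100), ("chr1", 300, 400), ("chr1", 900, 1000)])
    r2 = peaks([("chr1", 50, 150), ("chr1", 950, 1020)])
    r3 = peaks([("chr1", 120, 220), ("chr1", 390, 450)])
    # components: [0,220) (r1,r2,r3 chained via 50 and 120 overlaps),
    # [300,450) (r1,r3), [900,1020) (r1,r2)
    out = consensus_peaks([r1, r2, r3], min_support=2)
    expected = peaks([("chr1", 0, 220), ("chr1", 300, 450),
                      ("chr1", 900, 1020)])
    assert out.equals(expected)
    out3 = consensus_peaks([r1, r2, r3], min_support=3)
    assert out3.equals(peaks([("chr1", 0, 220)]))


def test_consensus_validates_arguments():
    rep = peaks([("chr1", 0, 100)])
    with pytest.raises(ValueError):
        consensus_peaks([rep], min_support=1)
    with pytest.raises(ValueError):
        consensus_peaks([rep, rep], min_support=3)


# ----------------------------------------------------------- retention
def test_retention_full_and_none():
    ref = peaks([("chr1", 0, 100), ("chr1", 500, 700)], mark="K4me3")
    full = classify_retention(ref, ref)
    assert full.percent_retained == 100.0
    none = classify_retention(ref, ref.iloc[0:0])
    assert none.percent_retained == 0.0
    assert none.n_reference == 2


def test_retention_counts_partition():
    rng = np.random.default_rng(0)
    ref = peaks([("chr1", int(s), int(s) + 200)
                 for s in rng.integers(0, 50_000, 100)])
    after = peaks([("chr1", int(s), int(s) + 200)
                   for s in rng.integers(0, 50_000, 40)])
    res = classify_retention(ref, after)
    assert len(res.retained) + len(res.lost) == len(ref)
    assert res.n_retained == len(res.retained)


def test_retention_translation_invariance():
    rng = np.random.default_rng(1)
    ref = peaks([("chr1", int(s), int(s) + 300)
                 for s in rng.integers(0, 50_000, 50)])
    after = peaks([("chr1", int(s), int(s) + 300)
                   for s in rng.integers(0, 50_000, 20)])
    base = classify_retention(ref, after)
    shift = 12_345
    shifted = classify_retention(ref.assign(start=ref["start"] + shift,
                                            end=ref["end"] + shift),
                                 after.assign(start=after["start"] + shift,
                                              end=after["end"] + shift))
    assert base.n_retained == shifted.n_retained


def test_retention_mark_mismatch():
    ref = peaks([("chr1", 0, 100)], mark="K4me3")
    after = peaks([("chr1", 0, 100)], mark="K27me3")
    with pytest.raises(ValueError, match="mark"):
        classify_retention(ref, after)


def test_printed_retention_rounding():
    res = RetentionResult(retained=pd.DataFrame(), lost=pd.DataFrame(),
                          n_reference=55854, n_retained=13214)
    assert round(res.percent_retained) == 24


# ------------------------------------------------------------------ KS
def test_ks_identical_and_disjoint():
    d, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert d == 0.0 and p == 1.0
    d, p = ks_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert d == 1.0


def test_ks_empty_rejected():
    with pytest.raises(ValueError):
        ks_compare([], [1.0])


def exhaustive_ks_p(a, b):
    """Permutation-exact two-sample KS p: enumerate all assignments of the
    pooled values into groups of size |a| and |b|."""
    pooled = np.asarray(list(a) + list(b))
    na = len(a)

    def ks_d(x, y):
        allv = np.sort(np.unique(pooled))
        cdf_x = np.searchsorted(np.sort(x), allv, side="right") / len(x)
        cdf_y = np.searchsorted(np.sort(y), allv, side="right") / len(y)
        return np.abs(cdf_x - cdf_y).max()

    observed = ks_d(np.asarray(a), np.asarray(b))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        total += 1
        if ks_d(x, y) >= observed - 1e-12:
            count += 1
    return count / total


@pytest.mark.parametrize("a,b", [
    ([1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5, 5.5]),
    ([0.1, 0.2, 0.9, 1.4], [0.15, 0.3, 0.35, 0.5]),
])
def test_ks_small_n_matches_exhaustive_enumeration(a, b):
    _, p = ks_compare(a, b)
    assert p == pytest.approx(exhaustive_ks_p(a, b), abs=1e-12)


# ----------------------------------------------------------- bivalency
def test_bivalency_disjoint_sets():
    k4 = peaks([("chr1", 0, 100)], hmd=90.0)
    k27 = peaks([("chr1", 5000, 5100)], hmd=95.0)
    cats = bivalency_classify(k4, k27)
    assert len(cats["bivalent"]) == 0
    assert len(cats["K4_only"]) == 1 and len(cats["K27_only"]) == 1


def test_bivalency_overlapping_sets():
    k4 = peaks([("chr1", 0, 100)], hmd=90.0)
    k27 = peaks([("chr1", 50, 150)], hmd=95.0)
    cats = bivalency_classify(k4, k27)
    assert len(cats["bivalent"]) == 2
    assert len(cats["K4_only"]) == 0 and len(cats["K27_only"]) == 0


def test_bivalency_requires_homogeneity():
    k4 = peaks([("chr1", 0, 100)], hmd=50.0)       # not homogeneous
    k27 = peaks([("chr1", 50, 150)], hmd=95.0)
    cats = bivalency_classify(k4, k27)
    assert len(cats["bivalent"]) == 0
    assert len(cats["K27_only"]) == 1


def test_bivalency_interleaved_brute_force():
    rng = np.random.default_rng(2)
    k4 = peaks([("chr1", int(s), int(s) + 300)
                for s in rng.integers(0, 20_000, 30)],
               hmd=rng.uniform(60, 100, 30))
    k27 = peaks([("chr1", int(s), int(s) + 300)
                 for s in rng.integers(0, 20_000, 30)],
                hmd=rng.uniform(60, 100, 30))
    cats = bivalency_classify(k4, k27)
    hk4 = k4[k4["hmd"] > 80].reset_index(drop=True)
    hk27 = k27[k27["hmd"] > 80].reset_index(drop=True)
    n_biv = 0
    for q in hk4.itertuples():
        if any(q.start < f.end and f.start < q.end for f in hk27.itertuples()):
            n_biv += 1
    for q in hk27.itertuples():
        if any(q.start < f.end and f.start < q.end for f in hk4.itertuples()):
            n_biv += 1
    assert len(cats["bivalent"]) == n_biv
    assert (len(cats["K4_only"]) + len(cats["K27_only"]) + n_biv
            == len(hk4) + len(hk27))


def test_category_retention_fraction_arithmetic():
    cat = {"K4_only": peaks([("chr1", i * 1000, i * 1000 + 100)
                             for i in range(4)], hmd=90.0, mark="K4me3")}
    after = {"K4me3": peaks([("chr1", i * 1000, i * 1000 + 100)
                             for i in range(3)])}
    fracs = category_retention_fractions(cat, after)
    assert fracs["K4_only"] == 0.75


def test_category_retention_empty_warns():
    cat = {"bivalent": peaks([], hmd=[], mark=[])}
    with pytest.warns(UserWarning, match="empty"):
        fracs = category_retention_fractions(cat, {})
    assert np.isnan(fracs["bivalent"])
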