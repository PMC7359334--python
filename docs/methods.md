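# Methods

## The synthetic sperm population

The simulator is the study's ground truth, not a fixture. A genome of
`n_chromosomes × chrom_length_bp` (default 2 × 300 kb) is tiled by 25-kb
cassettes — promoter (2 kb), exon (3 kb), intron (5 kb), enhancer
(1.5 kb), intergenic (13.5 kb) — and each region carries

* a **particle mixture** over (nucleosome, 110-bp subnucleosome, 70-bp
  subnucleosome): the heterogeneous baseline (0.50, 0.14, 0.36) matches
  the observed sperm MNase read split; homogeneous-nucleosome regions use
  (0.85, 0.05, 0.10) and homogeneous-subnucleosome regions
  (0.10, 0.20, 0.70);
* **true HMDs** for H3K4me3 and H3K27me3 in [0, 100]. Promoters cycle
  deterministically through six archetypes (high-K4, bivalent, high-K27,
  three heterogeneous/low profiles), giving planted cluster structure and
  gene sets.

Each of `n_cells` (default 100) cells draws one particle per 50-bp bin
from its region's mixture and independent Bernoulli methylation states per
mark at rate true-HMD/100. Everything downstream — MNase fragments,
IP/input libraries, the barcode ladder, replication — is sampled from this
one latent population.

**Randomness.** Every operation draws from a named substream of the master
seed (`SeedSequence([seed, crc32(name)])`), so adding an operation never
perturbs another's draws and all outputs are byte-reproducible from the
seed.

**Fragments.** Per bin, fragment count ~ Poisson(`depth`); each fragment
takes a uniformly sampled cell's particle, a length ~ Normal(class mean,
`frag_length_sd` = 8 bp) truncated to > 0, and a midpoint uniform in the
bin. The truncated-Normal keeps the three length classes separable at the
default windows; 8 bp reflects visually narrow gel bands. Fragments are
shifted inward at chromosome edges so coordinates stay valid.

**Calibrated ChIP.** The input library samples each (cell, bin) particle
with probability `depth / n_cells`; the IP captures methylated particles
with probability `ip_efficiency` (default 0.3) and unmethylated ones with
`ip_background` (default 0). The spike-in ladder (five barcodes per mark
at relative concentrations 0.25, 1, 4, 16, 64; `ladder_copies` = 5000
molecules at concentration 1 — the tier table is a documented stand-in, as
no canonical table exists) passes through the same capture model with
on-target members fully methylated. Hence the pooled on-target IP/input
ratio estimates efficiency/sampling-rate, and
HMD = 100·(IP/input)/efficiency recovers the true per-bin methylated
fraction; with `ip_background` > 0 the apparent HMD inflates by
(1 − m)·background/efficiency, reproducing the off-target inflation that
motivates calling the quantity *apparent*.

**Replication.** Peak-level survival, P(retain) = logistic(β₀ + β₁·HMD +
β₂·ln width) with defaults (−6, 0.06, 0.3): at a median 800-bp peak this
gives ~9% retention at HMD 30 and ~73% at HMD 85, a spread wide enough to
make retention analyses informative without degenerating. Replication is
modelled at peak, not nucleosome, level because all downstream analyses
operate on peaks.

## Inference components

**Fragment classes.** Closed length windows NUC [135, 175],
SUB110 [95, 125], SUB70 [55, 85] — ±15–20 bp around the nominal protection
lengths, disjoint, configurable. Fragments outside every window are
UNCLASSIFIED: excluded from statistics, counted in QC. Binning assigns
each fragment to the 50-bp bin containing its midpoint (unambiguous
conservation; overlap-weighting would blur counts at the sub-fragment
scale).

**Segmentation.** Layer 1 scores each bin's count vector under three
multinomial emission profiles; bins with fewer than `min_count` = 3
fragments are NO_DATA. Layer 2 is a 3-state HMM: initial emissions
(0.85, 0.05, 0.10) / (0.10, 0.20, 0.70) / genome baseline, self-transition
0.99 (domains span many bins), refined by Baum–Welch with a 0.5
emission pseudocount — the MAP update under a Dirichlet prior, and the
fitting history tracks the corresponding penalized log-likelihood, which
is provably non-decreasing (the raw likelihood can dip by ~1e-4 under the
penalty). Decoding is hard Viterbi (the analysis reports discrete region
classes); posterior marginals are exported for diagnostics. NO_DATA bins
are bridged with uniform emission during decoding but never reported as
homogeneous. Chromosomes are independent chains. The two subnucleosome
classes share one homogeneous-subnucleosome state because 110-bp particles
are rare and the biological contrast is nucleosomal vs subnucleosomal.

**HMD.** Efficiency is estimated from pooled on-target tier counts
(minimum-variance when tiers share the true ratio); the per-tier ratio CV
is a QC gate (warn above 0.25). Bins with input < `min_input` = 5 are NA —
not zero — so sparse bins cannot deflate band fractions. Values above 100
are kept. Peak HMD is the input-count-weighted mean of bin HMDs, which
algebraically equals the pooled-count ratio over the peak and is therefore
free of the per-bin ratio (Jensen) bias of ~+2% that an unweighted mean of
bin ratios would carry at 30 fragments/bin. Homogeneity is HMD > 80,
strict.

**Promoter clustering.** Genes × 20 bins × channels; minus-strand rows
reversed; genes within 2 kb of a chromosome edge dropped; genes with >50%
NA bins dropped, remaining NAs imputed with the channel median. Channels
are standardized to zero mean/unit variance before clustering in
continuous mode (HMD and enrichment fractions are on different scales;
switchable). PAM uses Euclidean dissimilarity on the flattened vector,
greedy seeded BUILD and full SWAP passes; the objective never increases,
so it terminates at a swap-local optimum. k defaults to 6 (the promoter
archetype count); no automatic k selection. Tests compare partitions by
adjusted Rand index, never raw labels.

**Randomization enrichment.** The null re-places each interval uniformly
on its own chromosome with length preserved; collisions between randomized
intervals are allowed (the simplest null consistent with observed/random;
GC- or mappability-matching is out of scope). Overlap is per-interval
(≥ 1 bp, half-open arithmetic), counted by binary search against merged
features — verified in tests against a quadratic all-pairs oracle.
Empirical p uses the add-one estimator, so p is never 0 and the smallest
achievable p with 1000 randomizations is 1/1001. No multiple-testing
correction across features: per-feature empirical p-values are reported
against a fixed threshold.

**Retention and bivalency.** Retained = ≥ 1 bp overlap with any
after-condition peak (configurable); replicate consensus keeps
overlap-chained components supported by ≥ 2 of 3 replicates and emits the
component span. Distribution comparisons always use reference-condition
HMD/width (what distinguished the peaks *before* replication). KS tests
delegate to scipy (`ks_2samp`, exact for small n). Bivalent = homogeneous
K4 peak overlapping homogeneous K27 peak (and vice versa); category
retention checks each peak against its own mark's after-set.

**Proportion test.** One-sample χ² score test,
z = (k/n − p0)/√(p0(1−p0)/n), one-sided p from the signed root; no
continuity correction by default (switchable). p0 comes from all genes
with usable promoters. The normal tail tracks the exact binomial tail
closely in the far tail (within 0.02 where exact p ≤ 0.05 for n ≥ 50) but
not at the distribution centre, where the binomial pmf lump at small n
exceeds any continuous approximation's reach; the unit suite pins the
estimator's exact algebraic properties and its far-tail agreement.

## Problem sizes

Tests and the acceptance script run the simulator at desk scale: 50–600 kb
genomes, 60–100 cells, depth 20–30, 20 replicate simulations for
estimator-recovery averages, 200 runs × 1000 randomizations for null
calibration, 6000 peaks for retention KS and 100 replicates for the
promoter fold-ratio. These sizes give standard errors comfortably inside
the asserted tolerances (e.g. region-level HMD recovery bias < 1 point at
depth 30 over 200 pooled bins).

## What the simulator does and does not emulate

It emulates: region-structured particle mixtures and methylation,
population-level sampling noise, IP capture with off-target background, a
concentration-graded barcode ladder sharing the capture model, and
HMD/width-dependent peak survival. It does **not** emulate base-level
sequence, sequencing error, mappability or GC structure, fragment-length
biases of library preparation, antibody lot variation, or peak-caller
behaviour on real signal (peaks come from a deliberately trivial
threshold-run caller, and synthetic peak sets used for retention analyses
are thinned to non-overlapping intervals as a real caller would emit).
Passing tests therefore demonstrate correctness of the estimators and
inference under the stated generative model — not robustness to artefacts
real sperm chromatin data may carry.

## Known limitations

* The HMM's exact original parameterization is not published; ours is a
  documented reconstruction, and genome-fraction outputs depend on its
  thresholds (`min_count`, self-transition) at low depth.
* Overlap-based retention calling is only meaningful for peak sets that
  are sparse relative to their widths; dense sets inflate retention.
* The ladder tier table and copy numbers are simulator conventions, not
  measured quantities.
* PAM is exact swap-local search, O(n²k) per pass: fine for promoter
  counts in the thousands, not for genome-wide bin matrices.
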