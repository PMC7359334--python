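# spermchrom

Analysis of **epigenetic homogeneity in sperm chromatin**: do most sperm
cells of a population carry the same chromatin feature at the same genomic
place? The package implements the computational pipeline for answering
that question from MNase-based sequencing data — and ships a fully
specified synthetic sperm-population simulator so every stage can be
validated against known ground truth.

It is written for computational epigeneticists working on sperm/gamete
chromatin, ICeChIP-style calibrated ChIP, or chromatin-state inference in
general.

## The science

*Xenopus* sperm retains a somatic-like complement of histone H3/H4, packaged
either as nucleosomes (~150 bp of MNase-protected DNA) or as
H2A/H2B-depleted subnucleosomes protecting ~110 or ~70 bp. Three questions
structure the analysis:

1. **Particle homogeneity.** Classify paired-end MNase fragments by insert
   length into (NUC, SUB110, SUB70); convert read fractions *f* to
   length-weighted genome coverage, cov_i = f_i·L_i / Σ_j f_j·L_j; bin the
   genome at 50 bp and segment it with a 3-state hidden Markov model
   (multinomial emissions over class counts; states: homogeneous
   nucleosome, homogeneous subnucleosome, heterogeneous ≡ genome baseline
   mixture), fitted by Baum–Welch and decoded by Viterbi.

2. **Methylation homogeneity.** Calibrated ChIP with a barcoded
   semi-synthetic nucleosome ladder converts IP enrichment into an
   absolute **apparent histone methylation density**,
   HMD = 100 · (IP/input) / (IP/input)_ladder, the percentage of H3 at a
   locus carrying the mark across the population. A locus or peak is
   *homogeneous* when HMD > 80 (strict). Promoters (TSS ± 2 kb, twenty
   200-bp bins) are clustered by PAM (k-medoids) over HMD and
   particle-state channels.

3. **Transmission.** Peak survival through egg-extract replication is
   modelled as logistic(β₀ + β₁·HMD + β₂·ln width); retained vs lost peaks
   are compared by two-sample Kolmogorov–Smirnov tests and by the ratio of
   randomization fold enrichments at genomic features (observed/mean of
   1000 length- and chromosome-preserving uniform re-placements; add-one
   empirical p). Gene-set association uses the one-sided χ² proportion
   test of a set's peak-category fraction against the genome-wide
   proportion.

The synthetic population makes all of this falsifiable: each of *n* cells
carries one particle per 50-bp bin drawn from region-specific mixtures and
per-mark methylation states at region-specific true HMD; fragments, IP
libraries, the spike-in ladder and replication are sampled from that
population, so estimator bias, segmentation accuracy and retention
recovery are measured against truth.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic population (seed 1, two 300-kb chromosomes, 100 cells, ~30
fragments/bin) and write their tables under `results/`:

```bash
python analysis/01_simulate_population.py
python analysis/02_fragment_classes.py
python analysis/03_segment_particles.py
...
python analysis/07_geneset_association.py
```

`02_fragment_classes.py` prints:

```
read fractions (classified): {'NUC': '52.2%', 'SUB110': '13.4%', 'SUB70': '34.4%'}
genome coverage (length-weighted): {'NUC': '66.8%', 'SUB110': '12.6%', 'SUB70': '20.6%'}
```

— half the reads but two thirds of the genome belong to nucleosomes, because
coverage weights each class by its protection length. `03_segment_particles.py`
decodes the particle states:

```
decoded state fractions: {'HOM_NUC': '7.3%', 'HOM_SUB': '2.7%', 'HET': '90.0%', 'NO_DATA': '0.0%'}
planted homogeneous fraction: 0.100; bin-level agreement with truth: 100.0%
HOM_NUC: strongest enrichment at enhancer (fold 6.69, empirical p 0.000999)
```

and `06_replication_retention.py` recovers the retention biology — retained
peaks carry higher methylation density, retention concentrates at
promoters, and homogeneous K4-marked peaks survive replication far better
than K27-only peaks:

```
K4me3: 20.4% of 607 peaks retained; retained-vs-lost KS: HMD D=0.526 (p=1e-25), ...
  promoter fold enrichment retained/lost: 3.33/0.24 = 14.07
category  n_peaks  fraction_retained
 K4_only       40              0.775
K27_only        3              0.333
bivalent       21              0.810
```

The same stages are available as a CLI (`spermchrom simulate | classify |
segment | hmd | promoters | enrich | retention | genesets | run-all`) and
as one call, `spermchrom.pipeline.run_pipeline(config, outdir)`, which
writes a manifest with per-output SHA-256 digests; reruns with the same
seed are byte-identical.

## Layout

```
src/spermchrom/     library: config, simulate, fragments, segmentation,
                    hmd, promoters, enrichment, retention, genesets,
                    intervals, io, pipeline, cli
analysis/           numbered narrative drivers (01–07)
tests/              pytest suite incl. exhaustive/brute-force oracles
scripts/acceptance.py
docs/methods.md     model assumptions, parameter defaults, limitations
```
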