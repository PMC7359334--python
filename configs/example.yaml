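seed: 1
n_chromosomes: 2
chrom_length_bp: 300000
bin_size_bp: 50
n_cells: 100
depth: 30.0
frag_length_means:
- 150.0
- 110.0
- 70.0
frag_length_sd: 8.0
region_specs: null
ip_efficiency: 0.3
ip_background: 0.0
ladder_tiers:
- - BCK4me31
  - K4me3
  - 0.25
- - BCK4me32
  - K4me3
  - 1.0
- - BCK4me33
  - K4me3
  - 4.0
- - BCK4me34
  - K4me3
  - 16.0
- - BCK4me35
  - K4me3
  - 64.0
- - BCK27me31
  - K27me3
  - 0.25
- - BCK27me32
  - K27me3
  - 1.0
- - BCK27me33
  - K27me3
  - 4.0
- - BCK27me34
  - K27me3
  - 16.0
- - BCK27me35
  - K27me3
  - 64.0
ladder_copies: 5000
retention_coefs:
- -6.0
- 0.06
- 0.3
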