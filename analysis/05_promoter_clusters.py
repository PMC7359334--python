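"""Cluster promoters (TSS +/-2 kb, 200-bp bins) by epigenetic profile.

Builds the genes x 20 bins x 4 channels matrix (HMD for each mark,
homogeneous-nucleosome and homogeneous-subnucleosome fractions), clusters
with PAM (k = 6), and checks the partition against the planted promoter
archetypes with the adjusted Rand index.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import warnings  # noqa: E402

import pandas as pd  # noqa: E402
from sklearn.metrics import adjusted_rand_score  # noqa: E402

from common import (all_marks, binned_mnase, build_population,  # noqa: E402
                    outdir, segmentation_for)

from spermchrom.io import write_tsv  # noqa: E402
from spermchrom.promoters import (build_promoter_matrix,  # noqa: E402
                                  cluster_mean_profiles, impute_and_filter,
                                  pam_cluster)


def main():
    cfg, genome, pop = build_population()
    counts = binned_mnase(cfg, genome, pop)
    _, _, states, _ = segmentation_for(counts)
    tracks, _ = all_marks(cfg, pop)
    states_track = counts[["chrom", "start", "end"]].assign(state=states)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # edge genes dropped
        matrix = build_promoter_matrix(
            genome.tss,
            {"HMD_K4": tracks["K4me3"], "HMD_K27": tracks["K27me3"]},
            states_track, chrom_sizes=genome.chrom_sizes)
    matrix = impute_and_filter(matrix)
    k = min(6, len(matrix.genes))
    result = pam_cluster(matrix, k=k, seed=cfg.seed)

    out = outdir()
    assign = result.assignments.rename_axis("gene_id").reset_index()
    truth = genome.tss.set_index("gene_id").loc[matrix.genes, "archetype"]
    assign["archetype_truth"] = truth.to_numpy()
    write_tsv(assign, out / "promoter_clusters.tsv",
              metadata={"k": k, "medoids": ",".join(result.medoids)})

    ari = adjusted_rand_score(truth.to_numpy(), result.assignments.to_numpy())
    print(f"clustered {len(matrix.genes)} promoters into {k} clusters "
          f"(total dissimilarity {result.total_dissimilarity:.1f})")
    print(f"adjusted Rand index vs planted archetypes: {ari:.3f}")
    cross = pd.crosstab(assign["cluster"], assign["archetype_truth"])
    print("cluster x archetype table:")
    print(cross.to_string())

    profiles = cluster_mean_profiles(result, matrix)
    rows = []
    for cl, prof in sorted(profiles.items()):
        for ci, ch in enumerate(matrix.channels):
            rows.append({"cluster": cl, "channel": ch,
                         **{f"bin{b:02d}": round(prof[b, ci], 3)
                            for b in range(prof.shape[0])}})
    write_tsv(pd.DataFrame(rows), out / "promoter_cluster_profiles.tsv")
    print("wrote promoter_clusters.tsv, promoter_cluster_profiles.tsv")


if __name__ == "__main__":
    main()
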