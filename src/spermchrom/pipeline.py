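"""End-to-end driver: simulate -> classify -> segment -> HMD -> promoters
-> enrichment -> retention -> gene sets.

Every stage is deterministic given the config seed, so rerunning (or
regenerating a deleted intermediate) reproduces byte-identical outputs;
the manifest records the digests that make this checkable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, fragments, genesets, hmd, promoters, retention
from . import segmentation as seg
from . import simulate as sim
from .config import SimConfig, MARKS, config_to_yaml
from .io import RunManifest, write_bed, write_bedpe, write_bedgraph, write_tsv

log = logging.getLogger("spermchrom")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: SimConfig, outdir, n_randomizations: int = 200) -> RunManifest:
    """Run the full synthetic analysis; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    manifest = RunManifest(config=_config_dict(config), seed=config.seed)

    genome, pop, mnase = _stage("simulate")(_simulate)(config, outdir, manifest)
    counts, baseline = _stage("classify")(_classify)(config, genome, mnase,
                                                     outdir, manifest)
    states, segments = _stage("segment")(_segment)(counts, baseline, outdir,
                                                   manifest)
    tracks, peak_sets = _stage("hmd")(_hmd)(config, pop, outdir, manifest)
    _stage("promoters")(_promoters)(config, genome, tracks, counts, states,
                                    outdir, manifest)
    _stage("enrich")(_enrich)(config, genome, segments, peak_sets,
                              n_randomizations, outdir, manifest)
    retained_sets = _stage("retention")(_retention)(config, peak_sets, outdir,
                                                    manifest)
    _stage("genesets")(_genesets)(genome, peak_sets, retained_sets, outdir,
                                  manifest)
    manifest.write(outdir / "manifest.json")
    return manifest


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["ladder_tiers"] = [list(t) for t in d["ladder_tiers"]]
    if d["region_specs"] is not None:
        d["region_specs"] = [asdict(s) if not isinstance(s, dict) else s
                             for s in config.region_specs]
    return d


def _simulate(config, outdir, manifest):
    genome = sim.generate_genome(config)
    pop = sim.simulate_population(config, genome)
    mnase = sim.simulate_mnase_fragments(config, pop)
    config_to_yaml(config, outdir / "config.yaml")
    manifest.register("config", outdir / "config.yaml")
    write_tsv(genome.regions, outdir / "regions_truth.tsv")
    manifest.register("regions_truth", outdir / "regions_truth.tsv")
    write_tsv(genome.tss, outdir / "tss.tsv")
    manifest.register("tss", outdir / "tss.tsv")
    for label in ("promoter", "enhancer", "exon", "intron", "intergenic"):
        path = outdir / f"features_{label}.bed"
        write_bed(genome.features(label), path)
        manifest.register(f"features_{label}", path)
    write_bedpe(mnase, outdir / "mnase_fragments.bed")
    manifest.register("mnase_fragments", outdir / "mnase_fragments.bed")
    return genome, pop, mnase


def _classify(config, genome, mnase, outdir, manifest):
    classified = fragments.classify_fragments(mnase)
    fracs = fragments.read_fractions(classified)
    cov = fragments.coverage_fractions(fracs)
    summary = pd.DataFrame({
        "particle_class": list(fracs),
        "read_fraction": list(fracs.values()),
        "coverage_fraction": [cov[c] for c in fracs],
    })
    write_tsv(summary, outdir / "class_fractions.tsv",
              metadata=fragments.qc_summary(classified))
    manifest.register("class_fractions", outdir / "class_fractions.tsv")
    counts = fragments.bin_counts(classified, config.bin_size_bp,
                                  genome.chrom_sizes)
    write_tsv(counts, outdir / "bin_counts.tsv",
              metadata={"n_rejected": counts.attrs["n_rejected"]})
    manifest.register("bin_counts", outdir / "bin_counts.tsv")
    baseline = np.array([fracs[c] for c in ("NUC", "SUB110", "SUB70")])
    return counts, baseline


def _segment(counts, baseline, outdir, manifest):
    params, history = seg.fit_hmm(counts, seg.default_params(baseline),
                                  max_iter=30)
    states, segments = seg.decode(counts, params)
    write_bed(segments.rename(columns={"state": "name"}),
              outdir / "segments.bed")
    manifest.register("segments", outdir / "segments.bed")
    fracs = seg.genome_state_fractions(segments)
    write_tsv(pd.DataFrame({"state": list(fracs), "fraction": list(fracs.values())}),
              outdir / "state_fractions.tsv",
              metadata={"loglik_final": history[-1], "n_iter": len(history)})
    manifest.register("state_fractions", outdir / "state_fractions.tsv")
    post = seg.posterior(counts, params)
    for i, state in enumerate(seg.STATES):
        track = counts[["chrom", "start", "end"]].assign(p=post[:, i].round(4))
        path = outdir / f"posterior_{state}.bedgraph"
        write_bedgraph(track, "p", path)
        manifest.register(f"posterior_{state}", path)
    return states, segments


def _hmd(config, pop, outdir, manifest):
    tracks, peak_sets = {}, {}
    for mark in MARKS:
        ip, inp, barcodes = sim.simulate_icechip(config, pop, mark)
        write_tsv(barcodes, outdir / f"barcodes_{mark}.tsv")
        manifest.register(f"barcodes_{mark}", outdir / f"barcodes_{mark}.tsv")
        eff, qc = hmd.capture_efficiency(barcodes, mark)
        write_tsv(qc, outdir / f"ladder_qc_{mark}.tsv",
                  metadata={"efficiency": eff, "tier_cv": qc.attrs["tier_cv"]})
        manifest.register(f"ladder_qc_{mark}", outdir / f"ladder_qc_{mark}.tsv")
        ip_bins = fragments.bin_counts(fragments.classify_fragments(ip),
                                       config.bin_size_bp, config.chrom_sizes())
        in_bins = fragments.bin_counts(fragments.classify_fragments(inp),
                                       config.bin_size_bp, config.chrom_sizes())
        track = hmd.hmd_track(ip_bins, in_bins, eff, mark=mark)
        tracks[mark] = track
        write_bedgraph(track.assign(hmd=track["hmd"].round(3)), "hmd",
                       outdir / f"hmd_{mark}.bedgraph")
        manifest.register(f"hmd_{mark}", outdir / f"hmd_{mark}.bedgraph")
        peaks = hmd.call_peaks(track)
        peaks = hmd.peak_hmd(peaks, track)
        peaks["homogeneity"] = hmd.homogeneity_call(peaks["hmd"].to_numpy())
        peaks["mark"] = mark
        write_tsv(peaks.round({"hmd": 3}), outdir / f"peaks_{mark}.tsv")
        manifest.register(f"peaks_{mark}", outdir / f"peaks_{mark}.tsv")
        peak_sets[mark] = peaks
        bands = hmd.hmd_band_fractions(track["hmd"])
        write_tsv(pd.DataFrame({"band": list(bands),
                                "fraction": list(bands.values())}),
                  outdir / f"hmd_bands_{mark}.tsv")
        manifest.register(f"hmd_bands_{mark}", outdir / f"hmd_bands_{mark}.tsv")
    return tracks, peak_sets


def _promoters(config, genome, tracks, counts, states, outdir, manifest):
    states_track = counts[["chrom", "start", "end"]].assign(state=states)
    matrix = promoters.build_promoter_matrix(
        genome.tss, {"HMD_K4": tracks["K4me3"], "HMD_K27": tracks["K27me3"]},
        states_track, chrom_sizes=genome.chrom_sizes)
    matrix = promoters.impute_and_filter(matrix)
    k = min(6, len(matrix.genes))
    result = promoters.pam_cluster(matrix, k=k, seed=config.seed)
    out = result.assignments.rename_axis("gene_id").reset_index()
    write_tsv(out, outdir / "promoter_clusters.tsv",
              metadata={"k": k,
                        "total_dissimilarity": round(result.total_dissimilarity, 6),
                        "medoids": ",".join(result.medoids)})
    manifest.register("promoter_clusters", outdir / "promoter_clusters.tsv")
    profiles = promoters.cluster_mean_profiles(result, matrix)
    rows = []
    for cl, prof in sorted(profiles.items()):
        for ci, ch in enumerate(matrix.channels):
            rows.append({"cluster": cl, "channel": ch,
                         **{f"bin{b:02d}": round(prof[b, ci], 4)
                            for b in range(prof.shape[0])}})
    write_tsv(pd.DataFrame(rows), outdir / "cluster_profiles.tsv")
    manifest.register("cluster_profiles", outdir / "cluster_profiles.tsv")


def _enrich(config, genome, segments, peak_sets, n_iter, outdir, manifest):
    chrom_sizes = genome.chrom_sizes
    feature_sets = {lab: genome.features(lab)
                    for lab in ("promoter", "enhancer", "exon", "intron",
                                "intergenic")}
    queries = {"segments_HOM_NUC":
               segments[segments["state"] == "HOM_NUC"][["chrom", "start", "end"]],
               "segments_HOM_SUB":
               segments[segments["state"] == "HOM_SUB"][["chrom", "start", "end"]]}
    for mark, peaks in peak_sets.items():
        queries[f"peaks_hmd80_{mark}"] = peaks.loc[
            peaks["homogeneity"] == "homogeneous", ["chrom", "start", "end"]]
    rows = []
    for qi, (qname, query) in enumerate(sorted(queries.items())):
        if len(query) == 0:
            continue
        table = enrichment.enrichment_table(query.reset_index(drop=True),
                                            feature_sets, chrom_sizes,
                                            n_iterations=n_iter,
                                            seed=config.seed + 1000 * qi)
        table.insert(0, "query", qname)
        rows.append(table)
    out = pd.concat(rows, ignore_index=True)
    write_tsv(out.round({"random_mean": 3, "random_sd": 3, "fold": 4,
                         "p_enrichment": 6, "p_depletion": 6}),
              outdir / "feature_enrichment.tsv")
    manifest.register("feature_enrichment", outdir / "feature_enrichment.tsv")
    return out


def _retention(config, peak_sets, outdir, manifest):
    rows = []
    retained_sets = {}
    for mark, peaks in peak_sets.items():
        after = sim.simulate_replication(peaks, config)
        retained_sets[mark] = after
        res = retention.classify_retention(peaks, after)
        row = {"mark": mark, "n_reference": res.n_reference,
               "n_retained": res.n_retained,
               "pct_retained": round(res.percent_retained, 2)}
        if len(res.retained) and len(res.lost):
            d_h, p_h = retention.ks_compare(res.retained["hmd"], res.lost["hmd"])
            d_w, p_w = retention.ks_compare(
                res.retained["end"] - res.retained["start"],
                res.lost["end"] - res.lost["start"])
            row.update(ks_D_hmd=round(d_h, 4), ks_p_hmd=p_h,
                       ks_D_width=round(d_w, 4), ks_p_width=p_w)
        rows.append(row)
    write_tsv(pd.DataFrame(rows), outdir / "retention_summary.tsv")
    manifest.register("retention_summary", outdir / "retention_summary.tsv")

    cats = retention.bivalency_classify(peak_sets["K4me3"], peak_sets["K27me3"])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fracs = retention.category_retention_fractions(cats, retained_sets)
    write_tsv(pd.DataFrame({"category": list(fracs),
                            "n_peaks": [len(cats[c]) for c in fracs],
                            "fraction_retained":
                            [round(v, 4) if v == v else v
                             for v in fracs.values()]}),
              outdir / "bivalency_retention.tsv")
    manifest.register("bivalency_retention", outdir / "bivalency_retention.tsv")
    return retained_sets


def _genesets(genome, peak_sets, retained_sets, outdir, manifest):
    k4 = peak_sets["K4me3"].assign(
        category=lambda d: "K4_" + d["homogeneity"].astype(str))
    k27 = peak_sets["K27me3"].assign(
        category=lambda d: "K27_" + d["homogeneity"].astype(str))
    peaks = pd.concat([k4, k27], ignore_index=True)
    flags = genesets.assign_peaks_to_genes(peaks, genome.tss,
                                           category_col="category")
    # archetype-truth gene sets stand in for ZGA / demethylase-sensitive lists
    sets = {
        "developmental_like": list(genome.tss.loc[
            genome.tss["archetype"].isin(["bivalent", "k27_high"]), "gene_id"]),
        "housekeeping_like": list(genome.tss.loc[
            genome.tss["archetype"] == "k4_high", "gene_id"]),
    }
    tests = genesets.gene_set_tests(flags, sets)
    write_tsv(tests.round({"p0": 4, "statistic": 4}),
              outdir / "geneset_tests.tsv")
    manifest.register("geneset_tests", outdir / "geneset_tests.tsv")
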