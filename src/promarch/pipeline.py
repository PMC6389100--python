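"""End-to-end synthetic study: generate, analyse, write every output table.

This is the package's smoke-test entry point and the template for real
analyses: it generates a seeded synthetic genome with planted promoter
archetypes, runs the full analysis chain (tpm normalisation, tag
clustering, shape/CpG classes, consensus promoters, SOM expression
classes, pairwise shift detection, k-mer and fixed-window motif scans,
gene/operon/SL annotation, SL-exclusion detection and array metagene
profiles) and writes each result as a TSV under ``outdir``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import annotation, arrays, clustering, consensus, io, motifs
from . import shifting, som, synthetic
from .synthetic import STAGES


def run_pipeline(outdir, seed: int = 0, n_chrom: int = 2,
                 chrom_len: int = 200_000, n_per_archetype: int = 12,
                 depth: int = 200_000, boot: int = 200) -> dict:
    """Run the whole pipeline on a seeded synthetic dataset.

    Returns a dict of the in-memory results; writes genome, annotation,
    per-stage CTSS tables, SL sites, probes, ground truth and every
    analysis table under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- synthetic study ---------------------------------------------
    genome, genes = synthetic.generate_genome(
        n_chrom=n_chrom, chrom_len=chrom_len, seed=seed)
    archetypes = synthetic.default_archetypes()
    truth = synthetic.plant_promoters(
        genome, genes, archetypes, n_per_archetype, seed=seed + 1,
        internal_archetypes=("male_sharp_tctaga",))
    ctss_raw = synthetic.simulate_cage(genome, truth, depth=depth,
                                       seed=seed + 2)
    sl_sites = synthetic.simulate_sl_sites(genome, truth, genes,
                                           fraction_sl=0.4, seed=seed + 3,
                                           n_exclusion=max(2, n_per_archetype // 4))
    probes = synthetic.simulate_array(genome, truth, probe_spacing=25,
                                      seed=seed + 4, noise_sd=0.1,
                                      dye_bias=1.3)
    genome.write_fasta(outdir / "genome.fa")
    io.write_gff3(genes, outdir / "genes.gff3")
    truth.to_json(outdir / "ground_truth.json")
    io.write_sl_sites(sl_sites, outdir / "sl_sites.tsv")
    io.write_probes(probes, outdir / "probes.tsv")
    for stage, df in ctss_raw.items():
        io.write_ctss(df, outdir / f"ctss_{stage}.tsv")

    # --- clustering and shape classes --------------------------------
    tables = {}
    clusters_by_stage = {}
    for stage, df in ctss_raw.items():
        df = df.copy()
        df.attrs["stage"] = stage
        tables[stage] = io.normalize_tpm(df)
        clusters_by_stage[stage] = clustering.cluster_ctss(tables[stage])
    pooled = [c for cs in clusters_by_stage.values() for c in cs]
    clustering.classify_shape(pooled)
    clustering.classify_cpg(pooled, genome)
    tc_frame = clustering.clusters_to_frame(pooled)
    tc_frame.to_csv(outdir / "tag_clusters.tsv", sep="\t", index=False)

    # --- consensus + SOM ----------------------------------------------
    cons = consensus.build_consensus(clusters_by_stage)
    expr = pd.DataFrame([cp.tpm_vector() for cp in cons],
                        index=[cp.id for cp in cons], columns=STAGES)
    som_assign = som.som_cluster(expr, grid=(5, 5), seed=seed)
    for cp in cons:
        if cp.id in som_assign.index:
            cp.som_unit = som_assign.loc[cp.id, "unit"]
    consensus.consensus_to_frame(cons).to_csv(
        outdir / "consensus_promoters.tsv", sep="\t", index=False)
    som_assign.to_csv(outdir / "som_units.tsv", sep="\t")

    # --- promoter shifting --------------------------------------------
    shifts = shifting.detect_shifts(cons, tables, "tailbud", "male")
    shifts.to_csv(outdir / "shifts_tailbud_male.tsv", sep="\t", index=False)
    counts = shifting.pairwise_shift_counts(cons, tables,
                                            stages=("tailbud", "day2", "male"))
    counts.to_csv(outdir / "shift_counts.tsv", sep="\t", index=False)

    # --- motifs --------------------------------------------------------
    male = clusters_by_stage["male"]
    seqs, center, ids = motifs.extract_windows(genome, male, flank=100)
    kmers = motifs.scan_kmers(seqs, center, k_range=(6,))
    kmers[6].ranking.head(50).to_csv(outdir / "hexamer_ranking.tsv",
                                     sep="\t", index=False)
    hits, present = motifs.search_fixed_window(seqs, center, "TCTAGA", (22, 52),
                                               ids)
    hits.to_csv(outdir / "tctaga_hits.tsv", sep="\t", index=False)
    tata_hits, _ = motifs.search_fixed_window(seqs, center, "TATAW", (22, 37),
                                              ids)
    tata_hits.to_csv(outdir / "tataw_hits.tsv", sep="\t", index=False)
    dinuc = motifs.dinucleotide_profile(seqs, center)
    dinuc.to_csv(outdir / "dinucleotide_profile.tsv", sep="\t")

    # --- annotation ----------------------------------------------------
    assign = annotation.assign_to_genes(pooled, genes)
    assign.to_csv(outdir / "gene_assignments.tsv", sep="\t", index=False)
    sl_status = annotation.classify_sl(genes, sl_sites, genome)
    sl_status.to_csv(outdir / "sl_status.tsv", sep="\t", index=False)
    internal = annotation.find_internal_promoters(pooled, genes, assign)
    internal.to_csv(outdir / "internal_promoters.tsv", sep="\t", index=False)
    exclusion = annotation.detect_sl_exclusion(male, sl_sites, genome)
    exclusion.to_csv(outdir / "sl_exclusion.tsv", sep="\t", index=False)

    # --- array profiles ------------------------------------------------
    track = arrays.normalize_probes(probes)
    track = arrays.smooth_track(track)
    track.to_csv(outdir / "probe_track.tsv", sep="\t", index=False)
    groups = {}
    for shape in ("broad", "sharp"):
        proms = [(p.chrom, p.strand, p.tss)
                 for p in truth.promoters.values() if p.shape == shape]
        prof = arrays.metagene(track, proms, group=shape, boot=boot,
                               seed=seed + 5)
        prof.to_frame().to_csv(outdir / f"metagene_{shape}.tsv",
                               sep="\t", index=False)
        groups[shape] = prof

    return {
        "genome": genome, "genes": genes, "truth": truth,
        "ctss": tables, "clusters": clusters_by_stage, "tag_clusters": tc_frame,
        "consensus": cons, "som": som_assign, "shifts": shifts,
        "shift_counts": counts, "kmers": kmers, "assignments": assign,
        "sl_status": sl_status, "internal_promoters": internal,
        "sl_exclusion": exclusion, "metagene": groups,
    }
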