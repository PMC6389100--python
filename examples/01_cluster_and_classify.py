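"""Tag clustering and sharp/broad promoter shapes on a synthetic study.

Generates a two-chromosome genome with planted sharp and broad
promoters, simulates six CAGE libraries, clusters CTSSes into tag
clusters and classifies their interquantile widths. The printed medians
show the planted architecture: sharp promoters (focused initiation)
have widths of a few bp, broad promoters (dispersed initiation over
~10 bp sd) widths of ~25 bp.
"""

import numpy as np

import promarch as pa

genome, genes = pa.generate_genome(n_chrom=2, chrom_len=200_000, seed=1)
truth = pa.plant_promoters(genome, genes, pa.default_archetypes(),
                           n_per_archetype=10, seed=2,
                           internal_archetypes=("male_sharp_tctaga",))
ctss = pa.simulate_cage(genome, truth, depth=100_000, seed=3)

pooled = []
for stage, df in ctss.items():
    table = pa.normalize_tpm(df)
    table.attrs["stage"] = stage
    clusters = pa.cluster_ctss(table)  # <1 tpm dropped, <=20 bp gap merge
    print(f"{stage:8s}: {len(clusters):3d} tag clusters")
    pooled.extend(clusters)

pa.classify_shape(pooled)           # pooled width quartiles
pa.classify_cpg(pooled, genome)     # CpG frequency quartiles
frame = pa.clusters_to_frame(pooled)

print("\nmedian interquantile width by shape class (bp):")
print(frame.groupby("shape_class")["iq_width"].median())
male = frame[(frame.stage == "male") & (frame.shape_class == "sharp")]
print(f"\nmale-stage sharp clusters: {len(male)}, "
      f"median width {male.iq_width.median():.0f} bp")
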