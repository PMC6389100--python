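"""Consensus promoter regions and SOM expression classes.

Merges per-stage tag clusters (>5 tpm, 100 bp gap rule) into consensus
promoter regions and clusters their six-stage expression profiles on a
5x5 self-organizing map. The male-specific planted archetype
concentrates in a single SOM unit; its unit label is printed along with
the unit occupancy table.
"""

import pandas as pd

import promarch as pa
from promarch.synthetic import STAGES

genome, genes = pa.generate_genome(n_chrom=2, chrom_len=200_000, seed=1)
truth = pa.plant_promoters(genome, genes, pa.default_archetypes(),
                           n_per_archetype=10, seed=2,
                           internal_archetypes=("male_sharp_tctaga",))
ctss = pa.simulate_cage(genome, truth, depth=100_000, seed=3)

clusters_by_stage = {}
for stage, df in ctss.items():
    t = pa.normalize_tpm(df)
    t.attrs["stage"] = stage
    clusters_by_stage[stage] = pa.cluster_ctss(t)

cons = pa.build_consensus(clusters_by_stage)
print(f"{len(cons)} consensus promoter regions")

expr = pd.DataFrame([cp.tpm_vector() for cp in cons],
                    index=[cp.id for cp in cons], columns=STAGES)
assign = pa.som_cluster(expr, grid=(5, 5), seed=4)
print("promoters per SOM unit:")
print(assign["unit"].value_counts().head(8))

# which unit holds the male-only planted promoters?
male_tss = {p.tss for p in truth.by_archetype("male_sharp_tctaga")}
male_ids = [cp.id for cp in cons
            if any(abs(d - t) <= 50 for d in cp.dominant.values()
                   for t in male_tss)]
units = assign.loc[assign.index.intersection(male_ids), "unit"]
print(f"\nmale-specific promoters fall in unit(s): {sorted(units.unique())}")
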