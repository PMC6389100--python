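"""Trans-splicing, operon-internal promoters and SL-exclusion events.

Simulates SL acceptor sites (AG immediately upstream, by construction)
including a subset placed so a planted TCTAGA's AGA coincides with the
acceptor. The analysis then classifies trans-spliced genes by the three
rules (window, count > 1, AG check), finds male-specific promoters
internal to operons, and detects the exclusion events where male
transcription initiates downstream of the acceptor.
"""

import promarch as pa

genome, genes = pa.generate_genome(n_chrom=2, chrom_len=200_000, seed=7)
truth = pa.plant_promoters(genome, genes, pa.default_archetypes(),
                           n_per_archetype=8, seed=8,
                           internal_archetypes=("male_sharp_tctaga",))
sl = pa.simulate_sl_sites(genome, truth, genes, fraction_sl=0.4, seed=9,
                          n_exclusion=4)
ctss = pa.simulate_cage(genome, truth, depth=150_000, seed=10)

status = pa.classify_sl(genes, sl, genome)
print(f"trans-spliced genes: {int(status.is_trans_spliced.sum())} "
      f"of {len(status)}")

clusters = pa.cluster_ctss(pa.normalize_tpm(ctss["male"]))
assign = pa.assign_to_genes(clusters, genes)
internal = pa.find_internal_promoters(clusters, genes, assign)
print(f"operon-internal promoters in the male: {len(internal)} "
      f"(planted: {sum(p.operon_internal for p in truth.promoters.values())})")

events = pa.detect_sl_exclusion(clusters, sl, genome)
print(f"SL-exclusion events (TCTAGA AGA = acceptor AG, TSS downstream): "
      f"{len(events)} (planted: 4)")
print(events[["cluster_id", "motif_start", "acceptor_pos", "dominant_pos"]]
      .to_string(index=False))
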