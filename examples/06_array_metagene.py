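"""Tiling-array normalisation and nucleosome metagene profiles.

Simulates two-channel probes with a phased nucleosome cosine (period
~175 bp, trough at the TSS) around broad promoters, a 1.5x dye bias and
Gaussian noise. Normalisation (biweight centring) removes the bias; the
metagene around broad promoters recovers the planted oscillation while
sharp promoters give a flat profile. Printed: residual bias, profile
extremes, and the CI half-width at the TSS.
"""

import numpy as np

import promarch as pa

genome, genes = pa.generate_genome(n_chrom=2, chrom_len=200_000, seed=11)
truth = pa.plant_promoters(genome, genes, pa.default_archetypes(),
                           n_per_archetype=10, seed=12)
probes = pa.simulate_array(genome, truth, probe_spacing=25, seed=13,
                           noise_sd=0.1, dye_bias=1.5)

track = pa.normalize_probes(probes)
print(f"raw mean log2 ratio {track.raw_log2.mean():+.3f} "
      f"(injected bias log2(1.5) = {np.log2(1.5):.3f})")
print(f"normalised mean     {track.norm_log2.mean():+.4f}")
track = pa.smooth_track(track)  # 150 bp running median, >=3 non-zero probes

for shape in ("broad", "sharp"):
    proms = [(p.chrom, p.strand, p.tss)
             for p in truth.promoters.values() if p.shape == shape]
    prof = pa.metagene(track, proms, group=shape, boot=500, seed=14)
    tss = prof.mean[np.argmin(np.abs(prof.offsets))]
    print(f"\n{shape}: n={prof.n_promoters}, profile range "
          f"[{prof.mean.min():+.2f}, {prof.mean.max():+.2f}], "
          f"value at TSS {tss:+.2f}")
print("\nbroad promoters show the planted trough (~-0.5) at the TSS and"
      "\n~175 bp phasing; sharp promoters stay near zero.")
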