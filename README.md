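# promarch

Promoter-architecture analysis of CAGE (Cap Analysis of Gene Expression)
transcription start site data across developmental stages, written for
regulatory genomics of compact chordate genomes where operons and
spliced-leader (SL) *trans*-splicing shape promoter usage.

Starting from per-position CTSS count tables (chrom, 1-based position,
strand, raw tag count; one table per stage), the package provides:

- **tpm normalisation and tag clustering** — CTSSes below 1 tpm are
  discarded, neighbouring CTSSes at most 20 bp apart merge into tag
  clusters (TCs), single-CTSS clusters below 5 tpm are dropped;
- **promoter shape** — the interquantile width `q0.9 − q0.1 + 1` of each
  cluster's signal, classified sharp/intermediate/broad by pooled width
  quartiles, plus CpG classes (LCG/HCG) from a 200 bp window on the
  dominant CTSS;
- **consensus promoters and expression classes** — TCs above 5 tpm merged
  across stages within 100 bp into consensus regions, whose six-stage
  expression profiles are clustered on a 5×5 self-organizing map (units
  labelled `row_col`, e.g. the male-specific `4_4` class);
- **promoter shifting** — for two samples A, B within a consensus region,
  the shifting score `max_x |F_A(x) − F_B(x)|` over the 5'→3' cumulative
  initiation fractions, a two-sample Kolmogorov–Smirnov test with
  effective sizes from raw tag counts, Benjamini–Hochberg FDR across
  promoters, and a shift call at score > 0.6 and FDR < 0.01;
- **position-specific core-promoter motifs** — exhaustive k-mer (k = 1–6)
  positional enrichment against a per-sequence composition null, IUPAC
  searches in fixed upstream windows (TATA-type elements in 37–22 bp,
  TCTAGA in 22–52/52–101 bp, ACCATAA in 32–72 bp), dinucleotide
  profiles, and PWM scanning of the 101 bp upstream region at 85%
  relative score;
- **SL / operon annotation** — gene assignment via gene body + 500 bp
  upstream windows, the three-rule *trans*-splicing call (positional
  window, tag count > 1, AG acceptor immediately upstream), detection of
  operon-internal promoters (operon position ≥ 2), and SL-exclusion
  events where a TCTAGA's AGA coincides with an acceptor and the TSS
  lies downstream of it;
- **tiling-array metagene profiles** — log2(Cy5/Cy3) centred on the
  Tukey-biweight mean, 150 bp running-median smoothing (≥ 3 non-zero
  probes), and mean profiles in 1000 bp windows around dominant TSSs
  with percentile-bootstrap 95% CIs over promoters;
- **a synthetic-data generator** — genomes with operons, planted sharp and
  broad promoter archetypes (motifs written at exact strand-aware
  upstream offsets), six-stage CAGE tag tables, SL acceptor sites and
  nucleosome-phased array probes, all with machine-readable ground
  truth, so every analysis stage is testable without external data.

Coordinates are 1-based and fully closed throughout; motif offsets are
measured from the motif's 5'-most base to the dominant TSS, strand-aware,
positive upstream.

## Worked example

```python
import promarch as pa

genome, genes = pa.generate_genome(n_chrom=2, chrom_len=200_000, seed=1)
truth = pa.plant_promoters(genome, genes, pa.default_archetypes(),
                           n_per_archetype=10, seed=2,
                           internal_archetypes=("male_sharp_tctaga",))
ctss = pa.simulate_cage(genome, truth, depth=100_000, seed=3)

pooled = []
for stage, df in ctss.items():
    t = pa.normalize_tpm(df); t.attrs["stage"] = stage
    pooled.extend(pa.cluster_ctss(t))
pa.classify_shape(pooled)
frame = pa.clusters_to_frame(pooled)
print(frame.groupby("shape_class")["iq_width"].median())
```

prints

```
shape_class
broad           27.0
intermediate    21.0
sharp            1.0
```

i.e. the planted broad promoters (initiation sd 10 bp) yield tag
clusters with ~27 bp interquantile widths while the planted sharp,
motif-driven promoters collapse to 1 bp — the sharp-versus-broad
dichotomy the width statistic is designed to expose. The scripts in
`examples/` walk through each capability (clustering, consensus + SOM,
shift detection, motif positions, SL/operon annotation, array
metagenes) the same way, printing the recovered numbers next to the
planted truth.

`promarch.run_pipeline(outdir, seed)` executes the whole chain on one
synthetic study and writes every analysis table (tag clusters,
consensus promoters, SOM units, shift calls, motif hits, gene/SL
annotation, metagene profiles) as TSVs.

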