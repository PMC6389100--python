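# Methods

This note records the models, conventions and numerical choices behind
`promarch`, and what the synthetic studies do and do not establish
about real data.

## Coordinates and strand conventions

All genomic coordinates are 1-based with fully closed intervals. Every
strand-aware quantity is defined in transcription (5'→3') order and
mapped back to genomic coordinates for storage: on the minus strand
"upstream" means higher genomic coordinates and sequence fetches return
the reverse complement. Motif offsets are measured from the motif's
5'-most base to the dominant TSS, positive upstream; a window quoted as
"37–22 bp upstream" is the closed offset interval [22, 37] (endpoint
inclusivity is our choice; the convention is audited by planting motifs
at known offsets and recovering them exactly).

## Tag clustering and promoter width

CTSS counts are normalised to tags per million (tpm) against the
library size, defaulting to the table's own total when the
mapped-library total is not supplied. Clustering is single-linkage
along the chromosome: CTSSes below 1 tpm are removed, retained CTSSes
on one chromosome and strand merge while consecutive positions are at
most 20 bp apart (inclusive gap — 20 bp merges, 21 bp splits), and
single-CTSS clusters below 5 tpm are dropped. These thresholds are the
field-standard CAGE defaults and are parameters of `cluster_ctss`.

The promoter width is the interquantile width: walking the cluster
5'→3', the lower/upper quantile positions are the first at which the
cumulative tpm reaches 10% / 90% of the total ("first position where
cumulative ≥ q·total" — deterministic on integer data; the convention
is ours and is pinned by an independent cumulative-sum oracle in the
tests). Width = q_up − q_low + 1 in genomic bp, so a single CTSS has
width 1. The dominant CTSS is the position of maximal tpm, ties broken
5'-most on the strand (tie frequency logged).

Shape classes use quartiles of width over the pooled cluster set (all
stages together, configurable): width ≤ Q1 is sharp, ≥ Q3 broad, else
intermediate; when Q1 = Q3 (degenerate pooled distribution) everything
is intermediate. A four-class scheme (quartiles plus the mean) exists
in the literature; the two middle classes are collapsed here because
only the extremes carry a distinct mechanistic interpretation. A
consequence worth stating: with quartile thresholds at most ~25% of
clusters can carry each extreme label, so on a synthetic 50/50
sharp/broad population "recovery" is scored as the absence of
cross-class confusion (a planted-sharp cluster never labelled broad and
vice versa), not as exact three-label agreement, which the quartile
rule cannot produce by construction. CpG classes (LCG/HCG) use the CG
dinucleotide frequency — count / (window − 1) — in a 200 bp window
centred on the dominant CTSS, again split by pooled quartiles.

## Consensus promoters and SOM expression classes

Tag clusters above 5 tpm enter the consensus merge as their
interquantile intervals; intervals on one chromosome and strand merge
across stages when the gap between them is at most 100 bp. The
consensus span is the union of merged intervals; per-stage expression
is the sum over member clusters, and each stage's dominant position and
width are taken from its highest-expressed member.

Expression profiles (six stages) are scaled to relative expression by
dividing each row by its maximum (z-scaling available behind a flag;
all-zero rows are excluded) and clustered on a rectangular 5×5
self-organizing map: Gaussian neighbourhood, radius decaying linearly
from half the grid size to 0.5, learning rate 0.5 → 0.01, 100 epochs of
online updates in a seeded random order, weights initialised from data
rows. Units are labelled `row_col`. Neither the topology nor the
hyper-parameters are canonical in the literature; the recovery test
(four planted archetype profiles at noise sd 0.1 recovered with
adjusted Rand ≥ 0.8 after majority mapping) validates these defaults,
not equivalence with any other SOM implementation. CTSS-level and
consensus-level SOMs are independent runs.

## Promoter shifting

For one consensus region and two samples, the score compares the 5'→3'
cumulative initiation fractions F_L (lower-total sample) and F_H: score
= max over positions of |F_L − F_H|, read as the fraction of the
lower-expressed sample's initiation lying upstream (F_L leading) or
downstream (F_H leading) of the other sample's initiation. It is 0 for
identical shapes, 1 for disjoint supports, invariant to uniform scaling
of either signal and symmetric under strand mirroring. This implements
the verbal "≥ 60% of initiation relocated" definition directly; other
toolkits differ in denominator details, so numeric equality with them
is not claimed.

Significance: a two-sample KS statistic on the same cumulative
fractions, with the asymptotic Kolmogorov distribution evaluated at
√(n_eff)·D where n_eff = n_A·n_B/(n_A + n_B) and the n are raw
(un-normalised) tag counts in the region — the natural effective sample
size for count-weighted empirical CDFs; a warning is logged when n_eff
< 10, where the asymptotics are unreliable (permutation p-values are
out of scope). Benjamini–Hochberg FDR is applied across all tested
promoters per stage pair; a shift is called at score > 0.6 and FDR <
0.01. Each result also carries the fractional overlap of the two
stages' interquantile intervals (intersection over the shorter
interval), so the "< 40% TC overlap" annotation can be applied
downstream. Promoters with zero signal in either sample are skipped and
logged.

## Motif analyses

All scans run on strand-oriented windows centred on dominant CTSSes
(200 bp for k-mer/dinucleotide scans, wider for densities). The
exhaustive k-mer scan counts every k-mer (k = 1–6) at every offset; the
expected count per offset is Σ_sequences Π_letters (per-sequence
mononucleotide frequency), a composition null that controls GC skew
without assuming positional structure, and k-mers are ranked by peak
positional enrichment (observed/expected). Windows containing N are
skipped and logged. IUPAC window searches record every hit offset; PWM
scanning uses log-odds against a uniform background with the relative
score (S − S_min)/(S_max − S_min) and a default threshold of 0.85 over
the 101 bp upstream region; log(0) cells (pseudocount 0) are replaced
by a large finite negative sentinel so the score arithmetic stays
finite while exact-consensus windows still score 1.0. PWMs are read
from MEME minimal format. Motif–expression association is reported in
both directions (% of each SOM class containing the motif; % of
motif-containing promoters per class) with a chi-square test of
independence, Yates correction off by default (available behind a
flag); a motif present everywhere or nowhere yields a degenerate table
and is reported with statistic 0, df 0, p 1.

## Gene, operon and SL annotation

A cluster is assigned to a gene when its dominant CTSS overlaps the
gene body or the 500 bp upstream region, strand-aware. When several
windows overlap, the gene with the nearest annotated start wins,
remaining ties going to the 5'-most gene — this tie rule is ours (the
convention is not settled in the field) and its frequency is logged. A
gene is *trans*-spliced when an SL site lies in the same window, has
tag count > 1, and shows AG immediately upstream in the reference;
classification depends only on the SL table, gene models and genome, so
it is idempotent and independent of the CAGE data. Operon-internal
promoters are clusters assigned to operon genes at position ≥ 2. An
SL-exclusion event requires the acceptor AG to coincide with TCTAGA
positions 4–5 (TCTAGA contains exactly one AG, so the anchoring is
unambiguous; the splice junction sits at motif base 6) and the dominant
CTSS at or 3' of the acceptor, so the transcript cannot contain it.
Mark–promoter intersection uses the window 500 bp upstream to 100 bp
downstream of a start site, any ≥ 1 bp overlap counting, with closed
intervals on both sides.

## Tiling arrays

Probe log ratios log2(Cy5/Cy3) are centred by subtracting the
sample-wide Tukey biweight mean (tuning constant c = 4.685, iterated
from the median with MAD scale to |Δ| < 1e-6; when the MAD is zero the
median is returned). Smoothing is a running median over a ±75 bp
genomic window (not probe index — the distinction matters at irregular
spacing and genomic distance is the physically meaningful one),
reported missing where fewer than 3 probes with non-zero value support
the window. Metagene profiles map probes within ±500 bp of each
dominant TSS to strand-aware offsets, binned at probe resolution
(the track's modal spacing) with no interpolation; the profile is the
mean per offset across promoters and the 95% CI a percentile bootstrap
resampling promoters — not probes — which matches the
CI-on-the-mean-across-promoters semantics of metagene plots. The CI is
widened, if necessary, to contain the point estimate, guarding the
ci_low ≤ mean ≤ ci_high invariant against percentile-bootstrap edge
cases. Promoters with mutually overlapping windows are excluded.

## The synthetic generator

The generator emulates the study design the analyses target: six
developmental stages (oocyte, tailbud, tadpole, day 2, adult female,
adult male), a small multi-chromosome genome (default 40% GC) with
~30% of genes in operons of 2–4 co-oriented genes, and six default
promoter archetypes — broad maternal/zygotic/ubiquitous promoters
(initiation sd 8–10 bp) and sharp adult/male/ubiquitous promoters
carrying TATAAA at 30 bp, TCTAGA at 44 bp and ACCATAA at 56 bp
upstream respectively, with the male archetype expressed only in the
final stage. These defaults mirror the canonical promoter taxonomy and
reported motif positions for this system; dispersion, depths and
fractions are parameters.

Sharp promoters emit 94% of tags at the dominant TSS and the rest
within ±2 bp; broad promoters draw from a discretised normal truncated
at ±4 sd. Per stage, promoter intensities are stage-profile weights
times gamma multipliers with mean 1 and variance 0.2 (the
negative-binomial mixing distribution), and exactly `depth` tags are
then drawn multinomially — giving NB-like overdispersion across
promoters while conserving the requested per-stage depth exactly,
which a direct per-promoter NB draw cannot do. SL sites are planted
with their AG written into the reference so the acceptor check passes
by construction; the exclusion subset places the acceptor at TCTAGA
base 6 so its AG is the motif's AG. Array probes carry a phased cosine
(amplitude 0.5, period 175 bp, trough at the TSS) within ±500 bp of
broad promoters, Gaussian noise, and a global multiplicative dye bias
on the Cy5 channel.

What the generator does **not** emulate: mapping artefacts and
multi-mapping bias, sequencing errors, promoter-to-promoter variation
in shape within an archetype, correlated noise between stages,
chromatin-driven background in the arrays, and genome-scale
heterogeneity (repeats, GC isochores). Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated model, not
robustness to every artefact of real CAGE or ChIP-chip data.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (numpy Generator) and
is byte-reproducible. The bundled studies use compact sizes chosen to
exercise each code path densely: oracle comparisons on 1,000 random
instances, architecture recovery with 100 + 100 planted promoters at
10k tags/stage, motif recovery with 500 planted TCTAGA promoters,
shift detection on 500 promoters with 50 planted shifts, SOM recovery
with 4 × 200 profiles, and CI coverage with 1,000 promoters over five
noise replicates. CI coverage is measured on the raw log ratios (dye
bias 1), whose per-offset truth is exactly the planted cosine; after
robust centring the truth would carry a small data-dependent offset
whenever planted signal occupies a large share of the array, which is a
property of the normalisation, not of the bootstrap being assessed.

## Known limitations

- The SOM is a minimal online Kohonen implementation; very large
  expression matrices would benefit from batch training.
- KS p-values are asymptotic; promoters with very few raw tags are
  flagged but still tested.
- The k-mer scan's composition null ignores dinucleotide structure, so
  CpG-related k-mers can appear mildly enriched genome-wide; positional
  peaks (the quantity used for ranking) are unaffected.
- `classify_sl` loops over genes and sites in Python; it is sized for
  compact genomes (thousands of genes), not mammalian annotation.
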